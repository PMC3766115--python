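"""Classify regulated genes into the two-level SFC/OFC scheme.

The packaged table maps functional roles to 45 Specific Functional
Categories nested in 10 Overall Functional Categories; roles that are
empty or unknown fall back to Miscellaneous.
"""

from rnaregulon import default_functional_map

fmap = default_functional_map()
print(f"{len(fmap.sfcs)} SFCs nested in {len(fmap.ofcs)} OFCs\n")

for role in [
    "Thiamin biosynthesis",
    "Cobalt transporters",
    "Glycine transporters",
    "",
    "uncharacterized membrane protein",
]:
    sfc, ofc = fmap.lookup(role)
    print(f"  {role or '(no role)':38s} -> SFC {sfc!r:40s} OFC {ofc!r}")
print("\nunknown roles stay visible in Miscellaneous rather than being")
print("silently reassigned by fuzzy matching.")
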