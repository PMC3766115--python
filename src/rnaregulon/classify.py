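"""Two-level functional classification of regulated genes.

Every gene in a reconstructed regulon is assigned a Specific Functional
Category (SFC) and, through it, an Overall Functional Category (OFC).
The mapping is data, not code: a TSV of ``functional_role -> SFC -> OFC``
rows ships with the package (45 SFCs nested in 10 OFCs) and can be
extended by the user.  Genes whose role is empty or not in the table
fall back to the "Other or unknown functional roles" SFC under the
"Miscellaneous" OFC.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources

from .model import Regulog, ValidationError

UNKNOWN_SFC = "Other or unknown functional roles"
MISC_OFC = "Miscellaneous"


def _normalize(role: str) -> str:
    return " ".join(role.split()).casefold()


@dataclass(frozen=True)
class CategoryCall:
    gene_id: str
    genome_id: str
    functional_role: str
    sfc: str
    ofc: str


class FunctionalMap:
    """role -> SFC and SFC -> OFC lookup with the Miscellaneous fallback.

    Role matching is exact after case and whitespace normalisation —
    unmapped roles surface visibly in Miscellaneous instead of being
    silently reclassified by fuzzy matching.
    """

    def __init__(self):
        self._role_to_sfc: dict[str, str] = {}
        self._sfc_to_ofc: dict[str, str] = {UNKNOWN_SFC: MISC_OFC}

    def add(self, functional_role: str, sfc: str, ofc: str) -> None:
        existing = self._sfc_to_ofc.get(sfc)
        if existing is not None and existing != ofc:
            raise ValidationError(
                f"SFC {sfc!r} mapped to two OFCs ({existing!r}, {ofc!r})"
            )
        self._sfc_to_ofc[sfc] = ofc
        if functional_role:
            self._role_to_sfc[_normalize(functional_role)] = sfc

    def validate(self) -> None:
        if MISC_OFC not in self._sfc_to_ofc.values():
            raise ValidationError(f"functional map lacks the {MISC_OFC!r} OFC")

    def sfc_of(self, functional_role: str) -> str:
        return self._role_to_sfc.get(_normalize(functional_role), UNKNOWN_SFC)

    def ofc_of_sfc(self, sfc: str) -> str:
        return self._sfc_to_ofc[sfc]

    def lookup(self, functional_role: str) -> tuple[str, str]:
        """Return the (SFC, OFC) pair for a functional role string."""
        sfc = self.sfc_of(functional_role)
        return sfc, self._sfc_to_ofc[sfc]

    @property
    def sfcs(self) -> set[str]:
        return set(self._sfc_to_ofc)

    @property
    def ofcs(self) -> set[str]:
        return set(self._sfc_to_ofc.values())


def default_functional_map() -> "FunctionalMap":
    """The packaged 45-SFC / 10-OFC classification table."""
    from . import io  # local import to avoid a cycle

    ref = resources.files("rnaregulon.data").joinpath("functional_categories.tsv")
    with resources.as_file(ref) as path:
        return io.read_functional_map(path)


def assign_categories(
    regulogs: list[Regulog], fmap: FunctionalMap
) -> dict[tuple[str, str], list[CategoryCall]]:
    """Assign every regulated gene an (SFC, OFC) pair.

    Returns calls keyed by ``(motif_id, taxgroup_id)``.  A gene regulated
    by the same motif through several operons is called once per motif;
    the same gene under two different motifs is called once per motif.
    """
    out: dict[tuple[str, str], list[CategoryCall]] = {}
    for regulog in regulogs:
        seen: set[tuple[str, str]] = set()
        calls: list[CategoryCall] = []
        for ro in regulog.regulated_operons:
            for gene in ro.operon.genes:
                key = (gene.genome_id, gene.gene_id)
                if key in seen:
                    continue
                seen.add(key)
                sfc, ofc = fmap.lookup(gene.functional_role)
                calls.append(
                    CategoryCall(
                        gene_id=gene.gene_id,
                        genome_id=gene.genome_id,
                        functional_role=gene.functional_role,
                        sfc=sfc,
                        ofc=ofc,
                    )
                )
        out[(regulog.motif_id, regulog.taxgroup_id)] = calls
    return out


def category_counts(
    assignments: dict[tuple[str, str], list[CategoryCall]],
    level: str = "SFC",
) -> dict[tuple[str, str], Counter]:
    """Gene counts per category for each (motif, taxgroup) cell."""
    if level not in ("SFC", "OFC"):
        raise ValueError(f"level must be SFC or OFC, got {level!r}")
    attr = "sfc" if level == "SFC" else "ofc"
    out: dict[tuple[str, str], Counter] = {}
    for key, calls in assignments.items():
        out[key] = Counter(getattr(c, attr) for c in calls)
    return out
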