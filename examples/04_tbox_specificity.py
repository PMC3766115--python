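"""Call T-box amino acid specificities from a multiple alignment.

The specifier codon of each T-box pairs with the tRNA anticodon, so
reading it off the alignment columns anchored by a reference sequence
and translating it gives the element's amino acid specificity.
"""

from rnaregulon import TBoxAlignment, call_specificity, map_anchor_columns

alignment = TBoxAlignment(
    rows={
        "ref":      "GGUGGUACGCAUCGAGGAC",
        "tbox_ile": "GGUGGUACGAUCCGAGGAC",   # AUC -> Ile
        "tbox_met": "GGUGGUACGAUGCGAGGAC",   # AUG -> Met
        "tbox_gap": "GGUGGUACGA-GCGAGGAC",   # gap in codon -> unresolved
    },
    reference_id="ref",
    reference_codon_span=(10, 11, 12),
)

print("anchor columns:", map_anchor_columns(alignment))
for call in call_specificity(alignment):
    if call.site_id == "ref":
        continue
    print(f"  {call.site_id}: codon={call.codon} -> {call.specificity_group}")
print("each resolved codon defines which uncharged tRNA the T-box senses.")
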