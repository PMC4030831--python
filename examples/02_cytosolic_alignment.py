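"""Cytosolic-tail alignment, identity summary, consensus and motif scan.

Aligns a small set of beta-integrin-like cytosolic tails, reports pairwise
identity statistics, derives the consensus, and scans for the NPxY/NxxY
tyrosine motifs that recruit phosphotyrosine-binding adaptors.
"""

from itbkit import (
    consensus_sequence,
    family_identity_summary,
    progressive_align,
    scan_cyto_motifs,
)
from itbkit.records import ProteinRecord

# Tails with the canonical architecture: membrane-proximal NPxY and a
# membrane-distal NxxY, diverging elsewhere.
tails = [
    ProteinRecord(id="tail_a", sequence="KLLMIIHDRREFAKFEKEKMNAKWDTGENPIYKSAVTTVVNPKYEGK"),
    ProteinRecord(id="tail_b", sequence="KLLMIIHDRREFAKFEKEKMNAKWDTGENPIYKSAVTTVVNPLYEGK"),
    ProteinRecord(id="tail_c", sequence="KLLMIIHDRREFARFEKEQMNAKWDTGENPIYKSAVTTVVNPKYEGK"),
    ProteinRecord(id="tail_d", sequence="KLLVTIHDRREFAKFEKEKMNAKWDTENPLYKSAITTVVNPKYEGK"),
]

msa = progressive_align(tails)
print(f"alignment: {msa.n_rows} rows x {msa.n_columns} columns")

summary = family_identity_summary(msa)
print(
    "pairwise identity: "
    f"min {summary['min_identity']:.1f}%  mean {summary['mean_identity']:.1f}%  "
    f"max {summary['max_identity']:.1f}%"
)
print(f"fully conserved columns: {summary['conserved_fraction']:.2f}")

print("consensus:", consensus_sequence(msa))

for rec in tails:
    hits = scan_cyto_motifs(rec.sequence, rec.id)
    pretty = ", ".join(f"{h.motif_class}@{h.start}" for h in hits)
    print(f"{rec.id}: {pretty}")
# Each tail shows the proximal NPxY; tail_b's NPLY distal motif is still an
# NPxY match, while a distal N..Y without the proline reports as NxxY.
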