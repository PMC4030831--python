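"""CpG-island detection and miRNA seed-site scanning on synthetic DNA.

Plants a CpG island in an AT-rich, CpG-depleted background, detects it, and
scans a synthetic 3' UTR for canonical miRNA seed-match sites.
"""

from itbkit import (
    NucleotideSequence,
    find_cpg_islands,
    plant_cpg_landscape,
    scan_mirna_seed_sites,
)
from itbkit.regulatory import reverse_complement

seq, truth = plant_cpg_landscape(20_000, [(8_000, 600)], seed=3)
(ts, te) = truth[0]
print(f"planted island (realised CpG bounds): {ts}-{te} ({te - ts + 1} bp)")

islands = find_cpg_islands(seq)
for isl in islands:
    print(
        f"detected island: {isl.start}-{isl.end} ({isl.length} bp), "
        f"GC {isl.gc_fraction:.2f}, obs/exp CpG {isl.obs_exp_cpg:.2f}, "
        f"{isl.cpg_count} CpGs"
    )
# Both thresholds (GC >= 0.5, obs/exp >= 0.6) hold over the whole reported
# region; the island name convention CpG<count> follows the CpG count.

mirna = "UGGAAUGUAAAGAAGUAUGUAU"  # a 22-nt mature miRNA, 5'->3'
core = reverse_complement(mirna.replace("U", "T")[1:8])
utr = "C" * 30 + core + "A" + "C" * 20 + core + "T" + "C" * 20
sites = scan_mirna_seed_sites(NucleotideSequence(id="utr", sequence=utr), mirna, "miR-x")
for site in sites:
    print(f"seed site: {site.site_type} at UTR position {site.start}")
# The first planted match carries both the position-8 pair and the A across
# from position 1 (8mer); the second has the position-8 pair but a U across
# from position 1, so it classifies as 7mer-m8.
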