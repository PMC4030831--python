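# itbkit

Comparative analysis of the vertebrate β-integrin (ITB/ITGB) gene and
protein family, as a tested, reusable Python library.

Integrins are heterodimeric αβ cell-adhesion receptors; vertebrates carry
eight β subunits (β1–β8) whose short cytosolic tails (β4 excepted) steer
both outside-in and inside-out signalling through conserved NPxY/NxxY
tyrosine motifs. `itbkit` implements the analyses that characterise this
family comparatively:

- **Sequence metrics** — gene spans from chromosome coordinates, average-mass
  molecular weight, isoelectric point by bisection over a Bjellqvist-pKa
  charge function.
- **Cytosolic-domain analysis** — domain extraction, Needleman–Wunsch/Gotoh
  pairwise and progressive multiple alignment (BLOSUM62, gap open 10 /
  extend 0.5), percent identity, consensus, NPxY/NxxY motif scanning.
- **Phylogenetics** — p-distances with pairwise gap deletion, the Kimura
  protein correction `d = −ln(1 − p − 0.2p²)`, Saitou–Nei neighbor joining,
  column-bootstrap clade support (default B = 100, display threshold 90),
  outgroup rooting on the nematode β-integrin homolog PAT3, and extraction
  of the family groups supported by the collapsed tree.
- **Subunit-pairing network** — ligand→receptor tables, per-β ligand and
  α-partner multiplicities, the shared-α graph, and a breadth-first
  evolutionary-path hypothesis rooted at the hemidesmosomal β4.
- **Regulatory scanning** — Gardiner-Garden/Frommer-style CpG-island
  detection (≥200 bp, GC ≥ 0.5, obs/exp CpG ≥ 0.6) and canonical miRNA
  seed-site classification (8mer / 7mer-m8 / 7mer-A1) on 3′ UTRs.
- **Synthetic data** — generators with exact ground truth for every stage:
  protein families evolving on a known tree under a 20-state equal-rates
  Poisson model, motif-planted tails, CpG landscapes, random pairing tables.

Two fixtures transcribed from the source study are packaged as TSV: the
vertebrate gene summary (coordinates, exon counts, subunit sizes) and the
ligand→receptor pairing table.

## Worked example

The core phylogenetic claim — eight monophyletic families falling into four
groups, rooted by the nematode sequence — is reproducible end to end on
synthetic data with known truth:

```sh
python examples/03_phylogeny.py
```

```
simulated 18 taxa x 370 columns (families >=0.6 substitutions/site apart)
true groups:      [['ITB1', 'ITB2', 'ITB7'], ['ITB3', 'ITB5', 'ITB6'], ['ITB4'], ['ITB8']]
recovered groups: [['ITB1', 'ITB2', 'ITB7'], ['ITB3', 'ITB5', 'ITB6'], ['ITB4'], ['ITB8']]
families monophyletic: True
```

The pipeline recovered every simulated family as a ≥90-support clade and
collapsed the unsupported backbone into exactly the four generating groups.
The pairing network reproduces the published multiplicities from the
packaged table:

```sh
python examples/04_pairing_network.py
```

```
beta  ligand_rows  alpha_partners
  b1       12            12
  b2        7             4
  b3        7             2
  b4        1             1
  ...
predicted paths from the ancestral beta-4:
  b4 -> b1  (shared alpha-6)
  b1 -> b3  (shared alpha-v)
  ...
  b7 -> b2  (immune-lineage fallback)
```

β1 binds the most ligand rows (12) and α partners, β4 only α6 — the basis
of the β4-ancestral hypothesis; the inferred paths radiate from β4 through
β1 to the αv-sharing cluster (β3/β5/β6/β8) and the immune pair (β7, β2).
The other examples (`01_sequence_metrics`, `02_cytosolic_alignment`,
`05_regulatory_scan`) exercise the remaining capabilities the same way.

A thin CLI wraps the pipeline for shell use:

```sh
itbkit simulate --seed 7 --out sim/
itbkit all --fasta sim/alignment.fasta --metadata sim/metadata.tsv \
           --outgroup OUTGROUP_t1 --seed 7 --out run/
itbkit pairing --root 4
```

Identical configuration and seed reproduce byte-identical outputs; the run
manifest records parameters and a checksum per output file.

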