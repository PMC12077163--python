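# archscan

Velvet-domain architecture from sequence conservation.

Velvet proteins (VeA, VelB, VelC, VosA and relatives) are NF-κB-like fungal
regulators whose shared velvet domain decomposes into an N-terminal
DNA-binding region (~30 aa), a poorly conserved variable region (0 to >400 aa),
and a C-terminal dimerization region (~100 aa) built from an α-subunit and a
β-subunit separated by a flexible linker.  `archscan` implements the
computational side of resolving that architecture from a large domain
collection:

* **Profile alignment** — a position-specific log-odds profile (bits against a
  background) built from a seed alignment, with a global affine-gap dynamic
  program as a desk-scale stand-in for a profile-HMM aligner, plus a bit-score
  filter for candidate screening.
* **Conservation scoring** — per match column *c* with residue distribution
  `p_c` and background `q`, the Jensen–Shannon divergence

  `JS(p_c, q) = ½·KL(p_c‖m) + ½·KL(q‖m)`, `m = ½(p_c + q)` (base-2 logs),

  gap-penalized by `(1 − gap_fraction)` and window-smoothed over a 3-column
  flank; plus sequence-logo information content
  `bits(c) = log2 20 − H(p_c)` and a conserved-column call at `bits > 2`.
* **Architecture segmentation** — threshold the smoothed JSD track to find the
  two conserved super-blocks (DNA-binding, dimerization), label the span
  between them *variable*, and split the dimerization block at its lowest
  internal conservation valley into α / linker / β.  Per-sequence region
  lengths count match occupancies plus insert residues, so variable regions
  of hundreds of residues are measured correctly.
* **Alanine-scan planning** — conserved columns inside chosen regions mapped
  onto a reference protein's residue numbering (skipping native alanines),
  and residue-correspondence tables across several references.
* **Structure contacts** — minimum polar heavy-atom (N/O) distances between
  residues of a dimer complex, for checking interface hydrogen bonds.
* **Synthetic families** — a generator that plants a fully known architecture
  and conservation structure (Dirichlet-categorical columns, near-invariant
  sites, calibrated variable-region and linker length distributions), so every
  stage is testable against ground truth.

## Worked example

Run the whole pipeline on a synthetic family of 500 domains:

```python
from archscan.pipeline import run_pipeline

summary = run_pipeline({"synthetic": {"n_sequences": 500, "seed": 11},
                        "outdir": "demo_out"})
print(summary["template"])
print(summary["n_conserved_dimerization"],
      summary["variable_percent_in_range"],
      summary["linker_percent_in_range"])
```

prints

```
{'dna_binding': [1, 30], 'variable': [31, 80], 'alpha': [81, 125],
 'linker': [126, 145], 'beta': [146, 185]}
30 47 66
```

meaning: the segmenter recovered the five-region architecture over the 185
match columns (DNA-binding 1–30, variable 31–80, α 81–125, linker 126–145,
β 146–185); 30 dimerization columns exceed 2 bits (exactly the planted
near-invariant sites); 47% of the 500 sequences have variable-region lengths
in 40–60 aa and 66% have linker lengths in 15–25 aa (the generator is
calibrated to 47%/63% at the distribution level; single-family percentages
fluctuate binomially).  `demo_out/` holds the aligned Stockholm file, the
conservation track, the logo matrix, the architecture and length tables, the
alanine-scan plan, and the resolved configuration.

The same stages are available from the shell:

```bash
archscan simulate --n 500 --seed 11 --out-prefix fam
archscan conserve --alignment fam.sto --out conservation.tsv --logo logo.tsv
archscan segment --alignment fam.sto --out architecture.tsv
archscan scan --alignment fam.sto --template architecture.tsv \
              --reference seq0001 --out scan.tsv
archscan contacts --structure complex.pdb --chain-a A --res-a 240 \
                  --chain-b B --res-b 110
```

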