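# gradcomm

Community-diversity analysis along local elevation gradients: from
georeferenced specimen tables with species-hypothesis labels to

- **incidence matrices** over configurable sample-units (locality, path,
  elevation bin, biome-by-threshold),
- **incidence-based richness estimation** — Chao2 (classic /
  bias-corrected with a CV switching rule), ICE, first/second-order
  jackknife, and sample-based rarefaction/extrapolation to a 3×
  effort target,
- **compositional similarity** (Sørensen, Jaccard, the J = S/(2−S)
  identity, and inference of integer shared-species counts from printed
  richness + similarity values),
- **beta-diversity partitioning** — turnover + nestedness and
  replacement + richness-difference families, pairwise and multi-site —
  plus UPGMA clustering (Newick export) and distance-decay analysis,
- **sliding-window ecotone detection** on 40-m elevation bins
  (shared-species index + species-exclusivity trends), and
- **agreement scoring** between two species partitions of the same
  specimens (agree / split / merge / complex).

A synthetic two-pool gradient-community generator with known ground
truth (`gradcomm.synthetic`) stands in for field data and drives the
parameter-recovery test suites. Reference constants for the Vietnamese
study site that motivated the defaults (locality coordinates, per-path
richness, printed similarity tables, delimitation agreement counts) live
in `gradcomm.datasets.nui_chua`.

## CLI

The `gradcomm` entry point exposes one subcommand per stage:

```sh
gradcomm simulate --seed 1 --out specimens.csv --truth-out truth.json
gradcomm incidence --input specimens.csv --hypothesis bptp --by path --out inc.tsv
gradcomm richness --input inc.tsv --factor 3 --boot 100 --seed 1 --out richness.tsv
gradcomm similarity --input inc.tsv --index both --out similarity.tsv
gradcomm beta --input inc.tsv --family both --cluster --out beta.tsv
gradcomm ecotone --input specimens.csv --hypothesis bptp --width 40 --out-prefix eco
gradcomm compare --input specimens.csv --reference morphospecies --test bptp --out cmp.json
gradcomm run --config pipeline.yaml      # end-to-end report bundle
```

All outputs are plain text (TSV/JSON/Newick). `gradcomm run` writes
incidence matrices, a richness table, a combined Sørensen/Jaccard
similarity matrix, beta-decomposition tables, a dendrogram, the ecotone
profile and call, a partition-comparison report, and a run log with the
seed and per-stage dropped-record counts.

## Layout

```
src/gradcomm/
  data_model.py   specimen tables, incidence matrices, biomes, geography
  synthetic.py    gradient-community generator + ground truth
  richness.py     frequency counts and richness estimators
  similarity.py   Sørensen/Jaccard and shared-count inference
  beta.py         beta partitions, UPGMA, distance decay
  ecotone.py      elevation slicing, sliding-window profile, ecotone call
  compare.py      species-partition agreement scoring
  pipeline.py     end-to-end orchestration
  cli.py          click CLI
  datasets/       study-site reference constants
tests/            pytest suite incl. acceptance criteria
scripts/          acceptance report generator
```
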