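# spatialsig

Spot-level spatial transcriptomics analysis of a regenerating-tissue region
of interest: region-vs-rest differential expression with an
expressing-fraction specificity ratio, three-criterion marker-signature
selection with reductive minimization, gene-set module scoring against
expression-binned random controls (including S/G2M cell-cycle phase
assignment), and a distance-to-reference-line gradient axis ("spatial time")
with per-sample scaling, pooling and binned profiles. A synthetic
Visium-like data generator with planted ground truth makes every stage
testable offline.

## Layout

| module | contents |
| --- | --- |
| `spatialsig.core_io` | `SpotDataset` and MTX/positions/regions/polyline readers and writers, QC metrics |
| `spatialsig.preprocessing` | depth normalization + log transform |
| `spatialsig.differential_expression` | region-vs-rest Wilcoxon DE, expressing fractions, specificity ratio, DEG set overlaps |
| `spatialsig.signature_selection` | top-K criterion flags, tiered signature selection, reductive prefixes |
| `spatialsig.scoring` | control-binned module scores, cell-cycle scoring and phase calls, score contrasts |
| `spatialsig.spatialtime` | point-to-polyline distances, per-sample scaled axis, binned profiles, two-group profile contrasts |
| `spatialsig.synthetic_data` | negative-binomial lattice generator with planted region/gradient/cycle programs and truth tables |
| `spatialsig.pipeline_cli` | YAML-configured end-to-end pipeline with deterministic CSV artifacts |

Packaged gene lists (`spatialsig/resources/gene_lists/*.txt`, one symbol per
line, `#` comments) include standard S/G2M cell-cycle programs and
provisional KEGG-derived pathway modules (glycolysis, OxPhos, hypoxia, VEGF,
vascular markers, TGFβ/BMP/WNT/Hippo, TCA, ETC complexes, mitophagy, fatty
acid metabolism). The pathway lists are placeholders meant to be reviewed
and edited for any real analysis.

## CLI

```bash
# synthetic dataset with ground-truth tables
spatialsig generate --seed 1 --out data/

# per-spot QC
spatialsig qc --counts data/matrix.mtx --positions data/positions.csv \
    --regions data/regions.csv --out qc.csv

# region-vs-rest DE
spatialsig de --counts data/matrix.mtx --positions data/positions.csv \
    --regions data/regions.csv --target blastema \
    --reference boundary --reference digit --out de.csv

# signature from a DE table
spatialsig signature --de-table de.csv --k-top 200 --size 100 --out signature.csv

# module scoring (builtin or file gene lists)
spatialsig score --counts data/matrix.mtx --positions data/positions.csv \
    --regions data/regions.csv --gene-list builtin:glycolysis --out scores.csv

# distance-to-reference axis
spatialsig spatialtime --counts data/matrix.mtx --positions data/positions.csv \
    --regions data/regions.csv --polylines data/polylines.csv \
    --include-region blastema --include-region boundary --out st.csv

# everything, from one YAML config
spatialsig run --config config.yaml --out artifacts/
```

A minimal two-condition synthetic config:

```yaml
seed: 5
synthetic:
  conditions:
    young: {seed: 21}
    aged: {seed: 22}
de:
  contrasts:
    - {name: blastema_vs_rest, target: blastema, reference: [boundary, digit, bone]}
signature: {contrast: blastema_vs_rest, k_top: 200, size: 100, sizes: [100, 50, 25, 10, 5]}
modules:
  blastema_signature: signature
  planted_program: planted:blastema_program
scoring: {n_bins: 24, n_ctrl: 100, contrasts: [[blastema, digit]]}
cell_cycle: {s_genes: planted:cycle_s, g2m_genes: planted:cycle_g2m}
spatialtime:
  include_regions: [blastema, boundary]
  n_bins: 10
  group_a: [young]
  group_b: [aged]
```

Reruns with the same config and seed produce byte-identical artifacts.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the seven acceptance criteria (rank-sum
exactness vs brute-force enumeration, distance-oracle equivalence and
rigid-motion invariance, planted-signature recovery, module-score
calibration, cell-cycle phase recovery, gradient profile recovery, and
end-to-end determinism).

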