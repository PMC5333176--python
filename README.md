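# sseview

Comparative 2D visualization of protein secondary structures.

`sseview` superposes multiple protein chains onto a reference, matches
their secondary-structure elements (SSEs) by spatial distance and type,
aligns the SSE sequences with a greedy gap-insertion algorithm (plus an
optimal dynamic-programming oracle and a union-chain procedure for MD
trajectories), and renders the result as static SVG: the reference chain is
drawn completely straightened, and every aligned SSE glyph encodes its 3D
angle, shift and length relative to the corresponding reference SSE.
Helices are drawn as spirals, sheets as arrows, coils as lines, inserted
gaps as gray rectangles; a per-chain navigation strip (black segments for
gaps, interrupted lines at chain breaks) summarizes the full alignment.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` contains one test per acceptance criterion
(worked greedy example, identity suite, greedy-vs-optimal oracle
equivalence, parameter recovery, MD suite, Kabsch suite, rendering
determinism).

## Command line

```sh
# compare: superpose OTHER chains onto REF and render both views
sseview compare ref.pdb a.pdb b.pdb --mode both --out out.svg \
    [--range A:B] [--reference-chain ID] [--dssp FILE ...] \
    [--assume-aligned] [--sort rmsd|input] [--max-dist 8.0] \
    [--highlight SSE_ID] [--export-columns cols.tsv] [--scene-json s.json] \
    [--config config.yaml]

# md: union-chain alignment of a trajectory (multi-MODEL PDB or JSON)
sseview md traj.pdb --frames 0:10 --out md.svg

# synth: generate fixtures (PDB or JSON by extension; --seed required)
sseview synth chain --blocks C2,H10,C3,E5,C2 --seed 1 --out chain.pdb
sseview synth pair  --blocks C2,H10,C2 --rotate H1:30 --seed 1 \
    --out-ref ref.pdb --out-other other.pdb
sseview synth traj  --blocks C2,H8,C3,E4,C2,H2,C2 --n-frames 10 \
    --flex H1:15 --disappear H5:0.5 --seed 1 --out traj.json
```

Inputs are PDB files (ATOM records for the CA trace; HELIX/SHEET records
for the annotation) or the package's JSON chain format. A DSSP output file,
when given, overrides the PDB annotation (H/G/I → helix, E/B → sheet,
everything else → coil; this 3-state reduction is a conventional choice).
Chains of unequal length need either `--assume-aligned` (coordinates
already superposed externally, e.g. by a structural aligner) or an explicit
residue pairing through the API.

A YAML config file can preset `layout:`, `render:` and `correspondence:`
parameters (see `sseview.layout.LayoutConfig` and
`sseview.render.RenderConfig` for the keys); CLI flags win.

## Package layout

| module | contents |
| --- | --- |
| `sseview.structure_io` | domain model (Residue/SSE/ProteinChain/Trajectory), PDB + DSSP parsers, JSON chain format, PDB writer |
| `sseview.superpose` | Kabsch superposition, RMSD, juxtaposition ordering |
| `sseview.correspondence` | SSE centroid matching (order-consistent DP) and raw candidate relations |
| `sseview.gap_alignment` | greedy gap insertion, optimal DP oracle, multi-chain master columns, MD union chain |
| `sseview.layout` | glyph angle/shift/length geometry, scene assembly, navigation strip |
| `sseview.render` | deterministic SVG emission |
| `sseview.cli` | `sseview compare / md / synth` |
| `sseview.synthetic` | ideal-geometry generators, perturbations, trajectories, worked instances |
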