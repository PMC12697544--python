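# hippomorph

Slice-wise morphometry of hippocampal subfield label maps.

High-resolution postmortem MRI with histology-guided subfield segmentations
(SUB, PrS, PaS, CA1–CA3, DG, SRLM) is the reference material for in vivo
hippocampal segmentation protocols, but the measurements such studies report
— where subfields appear and disappear along the long axis, how the
subicular complex divides medially-laterally, where the SUB–CA1 border sits,
how CA fields project onto the SRLM "dark band" — are usually taken by hand,
slice by slice, in a viewer. `hippomorph` turns those procedures into a
tested, deterministic pipeline over NIfTI label volumes, for anatomists and
neuroimaging methodologists who want the same assays reproducibly on their
own labelled data.

## Measurements

All measurements run per coronal slice in a canonical frame
(+x medial→lateral, +y inferior→superior, +z anterior→posterior), with
distances between slices `z₁ < z₂` equal to `(z₂ − z₁)·dz` mm.

* **Longitudinal extent** — a subfield *appears* on the first slice with a
  connected cluster of ≥ 4 voxels (8-connectivity: edges or corners; a
  single voxel suffices when the slice anterior to it is a coverage gap),
  and *disappears* on the last slice with any voxel. The DG appears when a
  DG component is first fully ringed by DG/SRLM. Head length = anterior tip
  → uncal apex; total length = anterior tip → posterior tip; ratio =
  head/total × 100.
* **Subicular proportions** — on body slices at 10%…50% of total length
  posterior to the apex, the subicular cortex is traced along its
  medial-axis centerline from the SUB–CA1 interface to the medial PaS end;
  each region's share of the centerline length is its percentage of the
  subicular complex.
* **SRLM projection** — every SRLM voxel lateral to the most medial DG
  point is assigned the CA subfield of its nearest CA voxel; proportions
  are assigned counts over the lateral-SRLM total. When the SUB–CA1 border
  lies lateral to the medial DG point, the band stretch medial to the
  border midpoint stays unassigned and the proportions sum to < 1.
* **SUB–CA1 border position** — a vertical drop from the most medial
  CA3/DG voxel onto the SUB/CA1 cortex defines the medial anchor; the
  border-midpoint offset from the anchor is expressed as a (possibly
  negative) percentage of the full hippocampal width and of the DG width,
  at 0 mm and 20 mm posterior to the apex (±3 mm search window).
* **Digitations** — peaks of the superior-surface height profile with ≥ 2
  voxels prominence; anterior CA3 is classified as on-top / in-between /
  both relative to the peaks and medial / midpoint / lateral by footprint
  thirds.
* **Cohort statistics** — Mann–Whitney U (exact enumeration for n ≤ 16,
  tie-corrected normal otherwise) and Spearman's ρ (exact permutation for
  n ≤ 8), with Benjamini–Hochberg FDR applied separately within each
  analysis family; dementia-status tests use all cases, the remaining
  covariate tests only non-dementia cases.

A synthetic phantom generator (`hippomorph.phantom`) draws
hippocampus-like label volumes — DG disc, SRLM band, C-shaped CA ribbon
partitioned by angle, medially attached subicular strip, digitated head,
per-subfield longitudinal extents, optional coverage gaps — with every
measured quantity known from the construction, so the whole pipeline is
testable without any imaging data.

## Worked example

```bash
python examples/01_phantom_and_extents.py
```

```
appearance order (gap to previous subfield):
  SUB  at slice  10  +0.0 mm (0.0% of head)
  CA1  at slice  20  +2.0 mm (11.9% of head)
  PrS  at slice  23  +0.6 mm (3.6% of head)
  DG   at slice  38  +3.0 mm (17.9% of head)
  CA3  at slice  46  +1.6 mm (9.5% of head)
  PaS  at slice  60  +2.8 mm (16.7% of head)
  CA2  at slice  61  +0.2 mm (1.2% of head)

head length  16.8 mm
total length 44.0 mm
head/total   38.2%
```

The phantom's subfields appear in the canonical order
SUB–CA1–PrS–DG–CA3–PaS–CA2; each line gives the distance to the previously
appearing subfield in mm and as a percentage of head length — the two
scales such measurements are reported on. `examples/02`–`06` walk through
the subicular, SRLM-projection, border, digitation and cohort-statistics
assays the same way.

For file-based work there is a thin CLI:

```bash
hippomorph phantom --out case0/ --seed 42
hippomorph measure --volume case0/phantom.nii.gz --landmarks case0/landmarks.json \
    --hemisphere right --out case0.json
hippomorph cohort --manifest manifest.tsv --covariates covariates.tsv --out report/
```

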