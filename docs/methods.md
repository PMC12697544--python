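# Methods

## Coordinate conventions

Volumes are canonically oriented at load time: +x runs medial→lateral,
+y inferior→superior, +z anterior→posterior. The frame is
hemisphere-relative — left-hemisphere volumes are mirrored along x when
loaded — so "medial" always means "small x" and every measurement is
hemisphere-invariant by construction. `mirror()` flips the hemisphere flag;
the x-reversal it implies in world coordinates cancels against
re-canonicalization, which is what makes it an involution and keeps all
canonical-frame measurements identical on mirrored specimens.

Slice indices are 0-based. The distance between slices z₁ < z₂ is
(z₂ − z₁)·dz — an inter-slice distance, not an inclusive slice count; the
source material does not state which convention its slice counts use, so
the exclusive convention is a documented package choice. Anisotropic
spacing is accepted with a warning; all measurements assume isotropy
(default 0.2 mm, the resolution of the postmortem scans this pipeline is
modeled on).

Landmarks (anterior tip, uncal apex, posterior tip) require visual
identification of uncal tissue, so they are always a JSON sidecar input and
never auto-detected.

## Extent rules

Appearance uses a four-contiguous-voxel cluster rule with in-plane
8-connectivity (corners and edges both count); the threshold drops to one
voxel when the slice immediately anterior to the candidate is a coverage
gap, since a gap hides whether the subfield started earlier. 3D
connectivity is never used — every rule is per coronal slice. Disappearance
uses a one-voxel rule with no cluster threshold: posteriorly the convention
is simply the last segmented slice, and no posterior cluster rule exists to
mirror. The DG is special-cased: it is identified where grey matter is
first fully surrounded by the dark band, which on a label map reads as a DG
connected component whose entire 8-neighbourhood boundary is DG or SRLM.
SUB appearance is by definition the anterior-tip slice (the most anterior
hippocampal tissue is subicular); a missing SUB label there raises a QC
warning rather than an error. Runs of ≥ 5 consecutive uncovered slices are
flagged per case for QC, not auto-excluded. Tail presence offsets that are
not slice multiples round to the nearest slice, ties toward anterior.

## Subicular centerline

The manual procedure draws piecewise-linear lines bisecting the cortex of
each subicular region; "inflection point" has no algorithmic definition, so
the package replaces the construction with the medial-axis skeleton path of
the SUB∪PrS∪PaS mask — deterministic, curvature-adaptive, and identical in
the straight-strip limit. Spurs shorter than 3 pixels are pruned. The path
runs from the skeleton endpoint nearest the SUB–CA1 interface centroid to
the skeleton point nearest the medial extreme of the most medial present
region, and both ends are extended along their local tangent to the mask
boundary (skeletons recede from ribbon ends by about half the ribbon
thickness; tangent extension restores the full centerline without the
radial overshoot that anchoring to an extreme voxel would add).

Arclength is measured along a moving-average-smoothed polyline (window 5)
rather than by summing raw 8-connected steps, which would overestimate
curved ribbons by up to ~8%. On straight axis-aligned strips the estimate
is exact; on a quarter-annulus of centerline radius 20 voxels it is within
3% of πr/2. Whether the original manual measurements were chord lengths
between inflection points or true curvilinear lengths is ambiguous; the
smoothed centerline approximates the latter, and the difference is below
the discretization tolerance for realistic cortical curvature. Path points
where the region label changes split the crossing segment half-half between
the two regions.

## SRLM projection

"Projecting subfield borders across onto the band" is realized as
nearest-CA-voxel assignment via Euclidean distance transforms — the
flashlight metaphor defines no metric, and nearest-neighbour labeling is
its natural geometric reading. Ties across subfields are broken with
priority CA3 > CA2 > CA1 and affect only one-voxel border shells. "Lateral
to the most medial DG point" is a half-plane test on x. For the
border-lateral special case the band is parametrized by arclength along its
skeleton from its medial end (the endpoint nearest the subiculum); the
SUB–CA1 interface midpoint is projected to its nearest band voxel, and all
band voxels medial of that position stay unassigned. The denominator is
always the full lateral-SRLM count, so proportions then sum to less than
one. Slices missing the DG or lateral SRLM are skipped and logged, never
fatal for the case.

## Border position

The medial anchor drops from the most medial CA3-or-DG voxel (whichever is
more medial) straight down (−y) to the first SUB/CA1 voxel; if the inferior
march misses, a superior march is attempted with a warning (folded
geometry). The "midpoint, if at an angle" of the border is the mean x of
CA1 voxels 8-adjacent to SUB — the mean (not median) keeps the estimator
continuous under voxel jitter. Widths use a voxel-edge convention (lateral
edge at max-x + 0.5), applied to both the full and the DG reference width
so the ratio is convention-insensitive to first order; the measurement is
edge-to-anchor, a documented choice worth at most one voxel. The 0 mm
position is one slice posterior to the uncal apex, the 20 mm position is
apex + round(20/dz); unusable targets are replaced by the nearest usable
slice within ±3 mm (searched +1, −1, +2, …), else the offset is absent for
the case. Negative percentages (border medial of the anchor) are
meaningful and preserved.

## Digitations

The classification operationalizes a visual judgment, so every threshold is
an explicit constant in `DigitationConfig`: superior-surface profile
smoothed over 3 columns, peaks at prominence ≥ 2 voxels, a CA3 column
counts as "on a peak" within ±w/4 of one (w = median peak spacing), on-top
at ≥ 70% of columns, in-between at ≤ 30%, both in between; position by
thirds of the footprint's medial-lateral extent with the bulk of CA3 taken
as the area-weighted column centroid. A featureless profile counts as one
digitation. Anterior CA3 is the first slice where a CA3 voxel rises above
the DG/SRLM top within ±1 column; without DG/SRLM on the slice the
footprint's median height substitutes, with a warning. Digitations are
counted on the anterior-CA3 slice by default.

## Statistics

Mann–Whitney U reports U = min(U_a, U_b) with midranks. The exact p-value
is the enumeration tail P(U ≤ U_obs) over all C(n_a+n_b, n_a) group
labelings; because min-U is symmetric in the groups this tail is already
two-sided (it matches scipy's exact two-sided p on untied data), and no
doubling is applied. Auto mode enumerates up to n_a+n_b = 16 and otherwise
uses the tie-corrected normal approximation with continuity correction.
Spearman's ρ uses midranks; the exact p enumerates all permutations of the
y-ranks for n ≤ 8. Benjamini–Hochberg is the step-up adjustment
min_{j≥i}(m/j·p₍ⱼ₎) capped at 1, applied separately within each analysis
family (head / total / ratio for lengths; offset × reference width for the
border), matching the way such families are corrected independently. The
significance level is 0.05 on adjusted p. Dementia-status tests use all
cases; sex, age, fixation-time and postmortem-interval tests are restricted
to cases without dementia. Missing covariates drop a case from that test
only, with per-cell n reported. An outlier-sensitivity rerun is available
via the 1.5×IQR rule and is labeled sensitivity-only.

## The phantom: what it emulates and what it does not

Each coronal slice is a concentric construction: a DG disc, an SRLM annulus
(full ring by default so the DG-enclosure rule has a target; optionally an
arc coextensive with the ribbon), a CA annulus cut open inferior-medially
and partitioned by angle CA1→CA2→CA3 running lateral→superior→medial, and a
horizontal subicular strip attached at the CA1 end, split lateral→medial
into SUB/PrS/PaS. Longitudinal extents, a linear medial ramp of the SUB–CA1
border, axially ramping sector spans, sinusoidal digitations of the
superior ring surface in head slices, slice dropout and boundary jitter are
all spec parameters; subicular extents must nest (PaS ⊆ PrS ⊆ SUB), which
reproduces the last-in-first-out disappearance pattern. Defaults (120 ×
120 × 250 voxels at 0.2 mm; head 16.8 mm, total 44 mm; strip fractions
0.46/0.38/0.16; CA sectors 150°/18°/12°) are sized to the magnitudes such
specimens show. Noise is applied after ground truth is computed, so
recovery under noise measures robustness rather than redefining truth.

Ground truth comes from the construction, not from the measurement path:
extents and lengths are closed-form; strip fractions are the drawn column
widths; SRLM fractions follow the construction's angle-sector rule
(including nearest-end assignment across the ribbon gap and the unassigned
stretch medial of the band start); border quantities come from the drawn
border column and direct mask extrema.

The phantom is deliberately idealized: straight long axis (the uncal apex
is only a landmark plane, with no uncal substructure and no tail
curvature), circular cross-sections, vertical SUB–CA1 interfaces, no
intensity image. Passing recovery tests therefore demonstrates that the
measurement rules are implemented correctly and are stable under
discretization, mirroring, translation and coverage gaps — not that they
are robust to the full anatomical variability of real specimens.

## Problem sizes in tests and the acceptance script

Recovery studies use randomized phantoms of 100×100×160 voxels (200 slices
for border studies so the 20 mm offset lies inside the body): 100 specs for
extent and border recovery, 50 for subicular and SRLM recovery in the test
suite; the acceptance script uses 40/20/20/30 specs per family and a
26-case cohort, sizes chosen so the whole pipeline re-runs in well under a
minute while keeping Monte-Carlo error far below the stated tolerances.
The null calibration simulates 1,000 cohorts at the 17/9 dementia split of
a 26-specimen cohort; the discrete U statistic makes the test intrinsically
slightly conservative (true type-I ≈ 0.046 at α = 0.05), which the
[0.035, 0.065] acceptance band accommodates.

## Known limitations

* The subicular centerline and the manual bisecting-line construction can
  differ on strongly curved or branching cortex; the skeleton path is the
  reproducible surrogate, not a re-implementation of rater behaviour.
* The exact extent of the unassigned SRLM stretch in the border-lateral
  case is a package convention (band-skeleton arclength ordering); the
  source procedure leaves it pictorial.
* Digitations are counted on the anterior-CA3 slice; counting on the most
  digitated head slice instead is supported by calling
  `digitation_profile` on any slice of interest.
* Statistics cells from real studies are not numerically reproduced: the
  underlying per-case values live in supplementary material, so the
  statistics layer is validated against enumeration oracles and null
  calibration instead.
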