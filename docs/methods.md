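# Methods

## Signal model

A sandwich-immunoassay antibody microarray is modelled at three levels.

**Spots.** Each capture antibody is printed as a replicate spot group
(default triplicate) inside one of 24 identical assay fields (3 × 8 layout).
Raw per-spot fluorescence is summarised per antibody by the **median** of
its replicates — robust to a single bad spot, which is the dominant failure
mode of triplicates. The replicate coefficient of variation is recorded and
flagged above 0.25; a group at or above the 16-bit scanner ceiling
(65535 a.u.) is flagged saturated.

**Background.** Blank spots (BSA, printing buffer, pre-immune antiserum) are
pooled and their group medians reduced to a single background *B* by a
second median. Per-antibody pre-immune values are kept for diagnostics but
do not enter *B* individually: the pooled estimate is more stable and the
pre-immune groups rarely differ systematically in practice. A signal is
**positive** iff it strictly exceeds `multiplier × B`, multiplier default
2.5; ties resolve negative. By default the positivity rule is applied after
within-chip control subtraction (buffer-only or heat-treated control), which
is the conservative order — subtraction can only lower a signal; the order
is configurable (`subtract_before_positivity`).

**Control subtraction** clips at zero (fluorescence is non-negative) and
records which control was used. The heat-treated control (500 °C bake)
destroys organics, so residual signal measures mineral-particle binding;
subtracting it from the untreated assay isolates the biological term.

## Cross-reactivity matrix

Column *j* of *G* comes from the single-immunogen assay of antibody *j*'s
cognate immunogen: `G_ij = (F_i − B) / (F_j − B)` on background-subtracted
signals, with `G_ij = 0` wherever spot *i* fails the positivity rule in that
assay and `G_jj = 1` by construction. Normalising with subtracted
backgrounds makes *G* exactly invariant under a uniform rescaling of one
assay's fluorescences (laser gain, tracer lot), which is the property a
ratio definition should have. Entries that pass positivity but fall below a
weak-link floor (default 0.01) are zeroed: at a typical cognate signal of a
few thousand a.u. they correspond to differences of a few counts above
background and are not reproducible. Antibodies whose cognate self-signal
fails positivity, or that are flagged poor performers in the panel
metadata, are pruned before matrix construction; the packaged 24-antibody
panel prunes to 16 (four EPS antibodies with no usable self-signal and the
four anti-protein antibodies that fail in sandwich format).

Each single-immunogen assay is reduced to one working concentration (the
curve maximum of its titration); *G* is a point estimate with no
uncertainty, matching how such matrices are used downstream.

## Deconvolution and classification

`F′` solves `G F′ = F` by LU factorisation. If `cond(G) > 1e8` (or *G* is
singular — e.g. two antibodies with identical cross-reaction columns), the
minimum-norm least-squares solution is returned with a warning and a flag
instead of an exception: field data must always yield a report. The
residual `‖G F′ − F‖` is carried in every report. `F′` is reported
unclipped; negative values are informative (over-explained spots).

Codes are assigned per antibody *i* with `θ_pos = multiplier × B` and
`θ_dec = dec_fraction × θ_pos`:

1. `F_i ≤ θ_pos` → **I**;
2. `F_i > θ_pos` and `F′_i ≤ θ_dec` → **II.a**, with an explanation list of
   in-array contributors `j ≠ i` with `G_ij > 0` and `F′_j > θ_dec`;
3. otherwise, B-type nodes → **III**;
4. A-type nodes run the forward-consistency check: every out-link `i → k`
   whose expected signal `G_ki × F′_i` exceeds `θ_pos` must satisfy
   `F_k ≥ consistency_tolerance × G_ki × F′_i`. All pass → **III**; any
   failure → **II.b**.

Numerical choices, all configurable:

- `dec_fraction = 0.5`. Because `G_jj = 1`, deconvoluted units are
  fluorescence units, so "F′ ≈ 0" is judged against half the positivity
  threshold: comfortably above solver noise, comfortably below any genuine
  positive signal.
- `consistency_tolerance = 0.5`: an observed cross-reaction may fall to
  half its predicted size (concentration and matrix effects) before it
  counts as a violation. Expected signals below `θ_pos` are never tested —
  an undetectably small prediction cannot fail a node.
- B-type nodes have no out-links, so their signal pattern cannot be probed
  for consistency; they never receive II.b. Where a B-type node's cognate
  is absent but a relative lights it, the call is II.a (the relative may or
  may not be on the array), which is the honest statement of what the graph
  can know.
- The decision tree is total and exclusive: every combination of the four
  binary conditions maps to exactly one code (enumerated in the tests).

## Calibration

The LOD is the lowest tested concentration whose cognate signal passes the
positivity rule, reported as a strict decade bound (`<10^k`) — the contract
of panel summary tables — or "not detected" when no point passes. No
interpolation between decades is attempted; the data do not support it.
Response curves are fitted with a three-parameter Langmuir isotherm
`F(c) = baseline + Fmax·c/(c + K)` (non-linear least squares, non-negative
bounds); it is also the generative form of the simulator, keeping fit and
simulation consistent. A 4PL slope parameter was deliberately not added:
none of the analyses here use curve shape beyond the plateau and the
threshold crossing. Non-convergent or flat fits (`Fmax ≈ 0`) are flagged,
never raised. The working tracer dilution is the smallest tested
concentration reaching 90% of the fitted plateau; a series still rising at
its top point is flagged as plateau-less.

## Synthetic data

The generator emulates one assay field of a scanner: per replicate spot of
antibody *i*,

```
intensity = background·ε0 + mineral·ε1 + [unless heat-treated] Σ_a R_ia · Fmax · c_a/(c_a + K_ia) · ε2
```

with independent unit-mean multiplicative lognormal factors ε (spot-level
CV default 10%, the standard regime for fluorescence scanners), background
100 a.u., and a relative-affinity matrix *R* (antibody × antigen, cognate
entries 1). Heat treatment zeroes the biological term only. All generators
are deterministic under a fixed seed.

The reference universe has 16 on-chip cognates wired with 28 directed
cross-reactivity links — the scale of the real array's graph — including
bidirectional lysate/EPS pairs for the four strains with retained EPS
antibodies, five strictly specific (B-type) antibodies, and three off-chip
relative antigens that bind a lysate spot without reproducing its cognate's
cross-reaction pattern (the II.b situation). The topology is fixed; the
seed jitters link weights by ±10%.

What the simulator does **not** model: spatial artefacts (comets, gridding
errors — the pipeline starts from per-spot intensities by design),
inter-slide batch effects, antigen-antigen competition for capture sites,
hook effects at extreme concentrations, and correlated replicate noise.
Passing synthetic benchmarks therefore demonstrates the correctness of the
quantification → matrix → deconvolution → classification chain under the
stated noise model, not robustness to those artefacts.

## Benchmark problem sizes

The presence-recovery benchmark scores 100 simulated multiplex samples
(4 random cognates each at saturating concentration, every third sample
plus one off-chip relative; cognate biological signal 10 × background;
replicate CV 10%) — 1600 antibody-sample pairs. The LOD benchmark scores 50
series with log-uniform random `Fmax` (≈500–20000 a.u.) and `K`
(10³–10⁵), decades 10²–10⁶, against the analytic noise-free threshold
crossing. The solver benchmark uses 200 random unit-diagonal 16 × 16
matrices with 28 off-diagonal entries, rejecting condition numbers above
10⁶ as not representative of real panels.

## Demonstration fixtures

No machine-readable signal values accompany the published field analyses,
so the packaged demonstration samples are synthetic constructions: observed
vectors built generatively as `F = G·s + d` (in-array presence strengths
`s`, off-chip direct contributions `d`) over the fixed 16-node matrix, tuned
so the classifier reproduces the per-antibody code tables reported for a
perchlorate-bioreactor extract and a high-Arctic hypersaline sediment.
They are regression fixtures for the classifier's qualitative behaviour,
not measurements.

## Known limitations

- *G* is a point estimate; no uncertainty is propagated into `F′` or the
  codes.
- The consistency check evaluates out-links independently; a node with many
  marginal violations passes if each individual link stays within
  tolerance.
- LOD bounds inherit the tested decade grid; a true LOD between decades is
  reported at the next tested decade above it.
- The linear mixing model assumes signals add; strong competition between
  related antigens for the same paratopes would violate additivity and is
  not modelled.
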