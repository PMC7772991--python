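"""Seeded end-to-end benchmarks on synthetic data.

These experiments run the full pipeline — simulate, quantify, deconvolve,
classify — under the study conditions the analysis assumes: the reference
16-antibody / 28-link universe, triplicate spots at 10% replicate CV, and
cognate biological signals ten times the background level.
"""

from __future__ import annotations

import numpy as np

from .calibration import estimate_lod
from .crossreact import CrossReactivityMatrix
from .deconv import DeconvolutionModel
from .quantify import estimate_background, summarize_replicates
from .simulate import (
    BindingModel,
    NoiseModel,
    SampleSpec,
    analytic_lod_decade,
    make_reference_universe,
    simulate_assay,
    simulate_dilution_series,
)

__all__ = ["presence_recovery", "lod_agreement"]

#: Background fluorescence of the benchmark assays (a.u.).
BACKGROUND = 100.0
#: Cognate biological signal at saturation: 10x the background level.
RECOVERY_FMAX = 10.0 * BACKGROUND


def presence_recovery(
    n_samples: int = 100,
    seed: int = 0,
    cv: float = 0.10,
    n_present: int = 4,
) -> dict:
    """Presence/absence recovery of the full pipeline on random samples.

    For each of ``n_samples`` seeded replicates, a random subset of
    ``n_present`` on-chip cognates is spiked at saturating concentration
    (biological signal 10x background); every third sample also contains
    one off-chip relative antigen. The multiplex assay is simulated at
    replicate CV ``cv``, quantified, deconvolved through the universe's
    true cross-reactivity matrix and classified. An antibody counts as
    recovered when (code == III) agrees with (cognate antigen present).

    Returns accuracy, the error count and the number of antibody-sample
    pairs scored.
    """
    binding = BindingModel(fmax=RECOVERY_FMAX, k=1e4)
    correct = total = 0
    confusion: dict = {}
    for i in range(n_samples):
        rng = np.random.default_rng((seed * 100_003 + i) % 2**31)
        universe = make_reference_universe(seed=i % 10)
        order = list(universe.antibody_order)
        model = DeconvolutionModel(
            CrossReactivityMatrix(tuple(order), universe.onchip_affinity_matrix())
        )
        present = set(rng.choice(order, size=n_present, replace=False))
        conc = {f"antigen-{c}": 1e7 for c in present}
        if i % 3 == 0:
            conc[str(rng.choice(universe.off_chip_antigens))] = 1e7
        table = simulate_assay(
            universe,
            SampleSpec(conc),
            binding=binding,
            noise=NoiseModel(
                background_mean=BACKGROUND, replicate_cv=cv, seed=seed
            ),
            seed=int(rng.integers(2**31)),
        )
        profile = estimate_background(summarize_replicates(table))
        results = model.fit(profile.f_vector(order), profile.background)
        for code in order:
            truth = code in present
            pred = results.presence[code] == "III"
            total += 1
            correct += pred == truth
            if pred != truth:
                key = (code, results.presence[code], truth)
                confusion[key] = confusion.get(key, 0) + 1
    return {
        "accuracy": correct / total,
        "errors": total - correct,
        "n_pairs": total,
        "confusion": confusion,
    }


def lod_agreement(
    n_series: int = 50,
    seed: int = 0,
    cv: float = 0.10,
    decades=(2, 3, 4, 5, 6),
) -> dict:
    """LOD estimation accuracy on seeded noisy dilution series.

    Each series draws a random binding amplitude and half-saturation
    constant, is simulated at replicate CV ``cv`` and its estimated LOD
    decade compared with the analytic threshold crossing of the noise-free
    curve. Reports the fraction of series within one decade.
    """
    rng = np.random.default_rng(seed % 2**31)
    universe = make_reference_universe(seed=0)
    order = list(universe.antibody_order)
    within = 0
    max_err = 0.0
    for i in range(n_series):
        fmax = float(10 ** rng.uniform(2.7, 4.3))  # ~500 .. 20000 a.u.
        k = float(10 ** rng.uniform(3.0, 5.0))
        binding = BindingModel(fmax=fmax, k=k)
        antibody = order[i % len(order)]
        series = simulate_dilution_series(
            universe,
            antibody,
            decades=decades,
            binding=binding,
            noise=NoiseModel(background_mean=BACKGROUND, replicate_cv=cv),
            seed=int(rng.integers(2**31)) // 1000,
        )
        est = estimate_lod(series)
        ref = analytic_lod_decade(decades, binding, BACKGROUND)
        if ref is None and est.decade is None:
            within += 1
            continue
        if ref is None or est.decade is None:
            # one detected, the other not: treat as off by the full range
            max_err = max(max_err, float(len(decades)))
            continue
        err = abs(est.decade - ref)
        max_err = max(max_err, err)
        if err <= 1.0:
            within += 1
    return {
        "fraction_within_one_decade": within / n_series,
        "max_decade_error": max_err,
        "n_series": n_series,
    }
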