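"""Deconvolution of multiplex immunoassay signals through the antibody graph.

The observed fluorescence of each spot is modelled as the sum of the
contributions of all antibodies that cross-react with it:

    F_i = sum_j G_ij * F'_j

so the deconvoluted signal vector F' solves G F' = F. Observed F is
non-negative; F' may be positive, zero or negative — a negative F' flags a
spot whose brightness is fully (over-)explained by cross-reaction.

Each antibody then receives a presence code:

* ``I``    — F at background level: cognate antigen absent.
* ``II.a`` — F positive but F' ~ 0: brightness explained by cross-reaction
  from an antigen that may or may not be on the array.
* ``II.b`` — F and F' positive, but the antibody's expected forward
  cross-reactions are missing: the cognate is absent and the signal comes
  from an unknown relative not represented on the array.
* ``III``  — F and F' positive with a consistent cross-reaction pattern:
  the cognate antigen (or a close relative) is present.

Only A-type antibodies (with out-going links) can be probed for the
forward-consistency pattern, so only they can receive ``II.b``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crossreact import AntibodyGraph, CrossReactivityMatrix, build_graph
from .quantify import DEFAULT_MULTIPLIER

__all__ = [
    "deconvolve",
    "classify",
    "explain",
    "DeconvolutionModel",
    "DeconvolutionResults",
    "DeconvolutionReport",
    "DEFAULT_DEC_FRACTION",
    "DEFAULT_CONSISTENCY_TOLERANCE",
    "COND_LIMIT",
]

#: F' threshold as a fraction of the positivity threshold. Deconvoluted
#: units are fluorescence units (G_jj = 1), so "F' ~ 0" is judged against
#: half the positivity threshold.
DEFAULT_DEC_FRACTION = 0.5
#: An out-neighbour passes the consistency check when its observed signal
#: is at least this fraction of the expected cross-reaction signal.
DEFAULT_CONSISTENCY_TOLERANCE = 0.5
#: Condition-number limit beyond which the solve falls back to a
#: minimum-norm least-squares solution.
COND_LIMIT = 1e8


def deconvolve(matrix: CrossReactivityMatrix, F) -> tuple[np.ndarray, dict]:
    """Solve G F' = F for the deconvoluted signal vector F'.

    Returns ``(F', info)`` where ``info`` holds the residual norm
    ``||G F' - F||``, the condition number and an ``ill_conditioned`` flag.
    For singular or ill-conditioned G (condition number above
    :data:`COND_LIMIT`) the minimum-norm least-squares solution is
    returned with a warning — field data must still produce a report.
    """
    F = np.asarray(F, dtype=float)
    G = matrix.G
    if F.shape != (matrix.n,):
        raise ValueError(f"F has shape {F.shape}, expected ({matrix.n},)")
    cond = float(np.linalg.cond(G))
    ill = not np.isfinite(cond) or cond > COND_LIMIT
    if ill:
        warnings.warn(
            f"cross-reactivity matrix ill-conditioned (cond={cond:.3g}); "
            "returning minimum-norm least-squares solution",
            RuntimeWarning,
            stacklevel=2,
        )
        f_prime, *_ = np.linalg.lstsq(G, F, rcond=None)
    else:
        f_prime = np.linalg.solve(G, F)
    residual = float(np.linalg.norm(G @ f_prime - F))
    return f_prime, {"residual": residual, "cond": cond, "ill_conditioned": ill}


@dataclass(frozen=True)
class AntibodyCall:
    """Classification of one antibody in one sample."""

    code: str
    F: float
    F_prime: float
    ab_type: str  # A or B
    presence: str  # I, II.a, II.b, III
    explanation: tuple = ()  # ((explaining antibody, contribution), ...)

    @property
    def full_code(self) -> str:
        if self.presence == "I":
            return "I"
        return f"{self.ab_type}.{self.presence}"


@dataclass(frozen=True)
class DeconvolutionReport:
    """Observed F, deconvoluted F', and per-antibody presence codes."""

    antibody_order: tuple[str, ...]
    F: np.ndarray
    F_prime: np.ndarray
    calls: tuple[AntibodyCall, ...]
    background: float
    residual: float
    ill_conditioned: bool = False
    thresholds: dict = field(default_factory=dict)

    def call(self, code: str) -> AntibodyCall:
        for c in self.calls:
            if c.code == code:
                return c
        raise KeyError(f"antibody {code!r} not in report")

    @property
    def presence(self) -> dict[str, str]:
        return {c.code: c.presence for c in self.calls}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            top = max(c.explanation, key=lambda e: e[1])[0] if c.explanation else ""
            rows.append(
                {
                    "antibody": c.code,
                    "F": c.F,
                    "F_prime": c.F_prime,
                    "ab_type": c.ab_type,
                    "presence_code": c.presence,
                    "top_explainer": top,
                    "residual": self.residual,
                }
            )
        return pd.DataFrame(rows).set_index("antibody")

    def to_tsv(self, path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t")

    def to_json(self, path=None) -> str:
        payload = {
            "background": self.background,
            "residual": self.residual,
            "ill_conditioned": self.ill_conditioned,
            "thresholds": self.thresholds,
            "antibodies": [
                {
                    "code": c.code,
                    "F": c.F,
                    "F_prime": c.F_prime,
                    "ab_type": c.ab_type,
                    "presence": c.presence,
                    "explanation": [
                        {"antibody": a, "contribution": v} for a, v in c.explanation
                    ],
                }
                for c in self.calls
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def classify(
    matrix: CrossReactivityMatrix,
    graph: AntibodyGraph,
    F,
    F_prime,
    B: float,
    multiplier: float = DEFAULT_MULTIPLIER,
    dec_fraction: float = DEFAULT_DEC_FRACTION,
    consistency_tolerance: float = DEFAULT_CONSISTENCY_TOLERANCE,
    residual: float = 0.0,
    ill_conditioned: bool = False,
) -> DeconvolutionReport:
    """Assign one presence code per antibody from (F, F').

    With theta_pos = multiplier * B and theta_dec = dec_fraction *
    theta_pos, antibody i is coded:

    1. ``I``    if F_i <= theta_pos;
    2. ``II.a`` if F_i > theta_pos and F'_i <= theta_dec (explained by
       in-array cross-reactors j with G_ij > 0 and F'_j > theta_dec);
    3. ``III``  if F_i > theta_pos, F'_i > theta_dec and i is type B;
    4. type-A nodes run the out-neighbour consistency check: every link
       i -> k whose expected signal G_ki * F'_i exceeds theta_pos must show
       F_k >= consistency_tolerance * G_ki * F'_i. All pass -> ``III``;
       any failure -> ``II.b`` (cognate absent; signal from an unknown
       off-array relative that does not reproduce the cognate's
       cross-reaction pattern).
    """
    if B is None or B <= 0:
        raise ValueError("background must be positive")
    if min(multiplier, dec_fraction, consistency_tolerance) <= 0:
        raise ValueError("thresholds must be positive")
    order = list(matrix.antibody_order)
    if list(graph.nodes) != order:
        raise ValueError("graph nodes do not match matrix antibody order")
    F = np.asarray(F, dtype=float)
    F_prime = np.asarray(F_prime, dtype=float)
    if F.shape != (matrix.n,) or F_prime.shape != (matrix.n,):
        raise ValueError("F / F_prime length must match the antibody order")

    theta_pos = multiplier * B
    theta_dec = dec_fraction * theta_pos
    G = matrix.G

    calls = []
    for i, code in enumerate(order):
        ab_type = graph.node_type(code)
        explanation: tuple = ()
        if F[i] <= theta_pos:
            presence = "I"
        elif F_prime[i] <= theta_dec:
            presence = "II.a"
            explanation = tuple(
                (order[j], float(G[i, j] * F_prime[j]))
                for j in range(matrix.n)
                if j != i and G[i, j] > 0 and F_prime[j] > theta_dec
            )
        elif ab_type == "B":
            presence = "III"
        else:
            consistent = True
            for k_code, w in graph.out_neighbors(code):
                expected = w * F_prime[i]
                if expected <= theta_pos:
                    continue  # undetectably small expected signal: no test
                k = order.index(k_code)
                if F[k] < consistency_tolerance * expected:
                    consistent = False
                    break
            presence = "III" if consistent else "II.b"
        calls.append(
            AntibodyCall(
                code=code,
                F=float(F[i]),
                F_prime=float(F_prime[i]),
                ab_type=ab_type,
                presence=presence,
                explanation=explanation,
            )
        )
    return DeconvolutionReport(
        antibody_order=tuple(order),
        F=F,
        F_prime=F_prime,
        calls=tuple(calls),
        background=float(B),
        residual=residual,
        ill_conditioned=ill_conditioned,
        thresholds={
            "multiplier": multiplier,
            "theta_pos": theta_pos,
            "theta_dec": theta_dec,
            "consistency_tolerance": consistency_tolerance,
        },
    )


def explain(
    report: DeconvolutionReport, matrix: CrossReactivityMatrix, antibody: str
) -> list[tuple[str, float]]:
    """Ranked decomposition of F_i into contributions G_ij * F'_j.

    Includes the self contribution; sorted descending. The contributions
    sum to F_i minus the solve residual on that coordinate.
    """
    order = list(matrix.antibody_order)
    if antibody not in order:
        raise KeyError(f"antibody {antibody!r} not in report")
    i = order.index(antibody)
    contribs = [
        (order[j], float(matrix.G[i, j] * report.F_prime[j]))
        for j in range(matrix.n)
        if matrix.G[i, j] > 0
    ]
    contribs.sort(key=lambda t: t[1], reverse=True)
    return contribs


class DeconvolutionModel:
    """Linear signal-unmixing model for one antibody array.

    Parameters
    ----------
    matrix : CrossReactivityMatrix
        The array's cross-reactivity matrix G.
    graph : AntibodyGraph, optional
        Derived from ``matrix`` when omitted.
    multiplier, dec_fraction, consistency_tolerance : float
        Classification thresholds; see :func:`classify`.
    """

    def __init__(
        self,
        matrix: CrossReactivityMatrix,
        graph: AntibodyGraph | None = None,
        multiplier: float = DEFAULT_MULTIPLIER,
        dec_fraction: float = DEFAULT_DEC_FRACTION,
        consistency_tolerance: float = DEFAULT_CONSISTENCY_TOLERANCE,
    ):
        self.matrix = matrix
        self.graph = graph if graph is not None else build_graph(matrix)
        if list(self.graph.nodes) != list(matrix.antibody_order):
            raise ValueError("graph nodes do not match matrix antibody order")
        self.multiplier = multiplier
        self.dec_fraction = dec_fraction
        self.consistency_tolerance = consistency_tolerance

    def fit(self, F, background: float) -> "DeconvolutionResults":
        """Deconvolve an observed profile and classify every antibody."""
        f_prime, info = deconvolve(self.matrix, F)
        report = classify(
            self.matrix,
            self.graph,
            F,
            f_prime,
            background,
            multiplier=self.multiplier,
            dec_fraction=self.dec_fraction,
            consistency_tolerance=self.consistency_tolerance,
            residual=info["residual"],
            ill_conditioned=info["ill_conditioned"],
        )
        return DeconvolutionResults(self, report, info)


class DeconvolutionResults:
    """Fitted deconvolution of one sample: F', codes, diagnostics."""

    def __init__(self, model: DeconvolutionModel, report: DeconvolutionReport, info: dict):
        self.model = model
        self.report = report
        self.f_prime = report.F_prime
        self.residual = info["residual"]
        self.cond = info["cond"]
        self.ill_conditioned = info["ill_conditioned"]

    @property
    def presence(self) -> dict[str, str]:
        return self.report.presence

    def to_frame(self) -> pd.DataFrame:
        return self.report.to_frame()

    def explain(self, antibody: str) -> list[tuple[str, float]]:
        return explain(self.report, self.model.matrix, antibody)

    def summary(self) -> str:
        th = self.report.thresholds
        lines = [
            "Deconvolution results",
            "=" * 64,
            f"antibodies: {len(self.report.antibody_order)}   "
            f"links: {self.model.graph.n_links}",
            f"background B = {self.report.background:g}   "
            f"theta_pos = {th['theta_pos']:g}   theta_dec = {th['theta_dec']:g}",
            f"residual ||G F' - F|| = {self.residual:.4g}   "
            f"cond(G) = {self.cond:.4g}"
            + ("   [ill-conditioned: min-norm LSQ]" if self.ill_conditioned else ""),
            "-" * 64,
            f"{'antibody':<10}{'F':>12}{'F_prime':>12}  {'type':<5}{'code':<8}"
            f"{'top explainer'}",
        ]
        for c in self.report.calls:
            top = max(c.explanation, key=lambda e: e[1])[0] if c.explanation else "-"
            lines.append(
                f"{c.code:<10}{c.F:>12.1f}{c.F_prime:>12.1f}  "
                f"{c.ab_type:<5}{c.presence:<8}{top}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Paired bar plot of observed F and deconvoluted F' per antibody."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        order = self.report.antibody_order
        x = np.arange(len(order))
        ax.bar(x - 0.2, self.report.F, width=0.4, color="black", label="F observed")
        ax.bar(x + 0.2, self.f_prime, width=0.4, color="tab:red", label="F' deconvoluted")
        ax.axhline(self.report.thresholds["theta_pos"], ls="--", lw=0.8, color="grey")
        ax.axhline(0.0, lw=0.8, color="black")
        ax.set_xticks(x)
        ax.set_xticklabels(order, rotation=90)
        ax.set_ylabel("fluorescence (a.u.)")
        ax.legend()
        for i, c in enumerate(self.report.calls):
            ax.annotate(
                c.full_code, (x[i], max(c.F, 0)), ha="center", va="bottom", fontsize=7
            )
        return ax
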