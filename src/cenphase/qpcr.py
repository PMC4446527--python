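"""Relative fold enrichment of IP over input DNA by the ΔΔCt method.

For each amplicon, ΔCt = mean(Ct_IP) - mean(Ct_input) over replicates;
ΔΔCt subtracts the same difference at a single-copy control amplicon
outside the enriched region, cancelling any plate-wide offset between the
two sample classes; log2 fold enrichment = -ΔΔCt.  Standard dilution
curves (Ct against log10 relative amount) provide quality control: a run
is reliable only when the calibration line's r² lies in [0.95, 1].
Amplification efficiency, 10^(-1/slope) - 1, is reported as metadata but
not used to correct fold estimates (pure 2^-ΔΔCt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import QpcrExperiment

__all__ = [
    "StandardCurveFit",
    "EnrichmentPoint",
    "fit_standard_curve",
    "qc_curve",
    "enrichment_profile",
    "plot_profile",
    "QC_R2_MIN",
]

QC_R2_MIN = 0.95


@dataclass
class StandardCurveFit:
    slope: float
    intercept: float
    r_squared: float
    efficiency: float


@dataclass
class EnrichmentPoint:
    """Enrichment at one amplicon; ``log_fold`` is in log2 units and equals
    ``-ddct`` exactly."""

    amplicon: tuple[int, int]
    delta_ct: float
    ddct: float
    log_fold: float
    delta_ct_sd: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isclose(self.log_fold, -self.ddct, atol=0.0, rtol=0.0):
            raise ValueError("log_fold must equal -ddct exactly")

    @property
    def fold(self) -> float:
        return float(2.0**self.log_fold)


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurveFit:
    """Least-squares line of Ct against log10(relative amount).

    ``points`` are (dilution factor, Ct) pairs, e.g. the 1:1, 1:10, 1:100
    input dilution series.  Efficiency = 10^(-1/slope) - 1 (1.0 for
    perfect doubling chemistry, slope -3.3219).
    """
    if len(points) < 3:
        raise ValueError("standard curve needs at least 3 points")
    dil = np.array([p[0] for p in points], dtype=float)
    ct = np.array([p[1] for p in points], dtype=float)
    if np.unique(dil).size < 3:
        raise ValueError("standard curve needs at least 3 distinct dilutions")
    x = np.log10(dil)
    fit = stats.linregress(x, ct)
    r2 = float(fit.rvalue**2)
    efficiency = float(10.0 ** (-1.0 / fit.slope) - 1.0) if fit.slope != 0 else float("nan")
    return StandardCurveFit(float(fit.slope), float(fit.intercept), r2, efficiency)


def qc_curve(r_squared: float) -> bool:
    """Reliability criterion: pass iff 0.95 <= r² <= 1 (inclusive)."""
    return QC_R2_MIN <= r_squared <= 1.0


def enrichment_profile(
    exp: QpcrExperiment, require_qc: bool = True
) -> list[EnrichmentPoint]:
    """Per-amplicon enrichment points, ordered by genomic position.

    ΔCt is the difference of replicate-mean Cts (IP minus input); ΔΔCt
    normalises by the control amplicon; log_fold = -ΔΔCt.  When standard
    curves are attached and ``require_qc`` is set, every amplicon's curve
    must pass the r² criterion.
    """
    by_amp: dict[tuple[int, int], dict[str, list[float]]] = {}
    for amp, sample, _rep, ct in exp.measurements:
        if ct <= 0:
            raise ValueError(f"non-positive Ct at amplicon {amp}")
        by_amp.setdefault(tuple(amp), {}).setdefault(sample, []).append(ct)

    control = tuple(exp.control_amplicon)
    if control not in by_amp or {"IP", "input"} - set(by_amp[control]):
        raise ValueError("control amplicon must be measured in both IP and input")

    if require_qc and exp.standard_curves:
        for amp, pts in exp.standard_curves.items():
            fit = fit_standard_curve(pts)
            if not qc_curve(fit.r_squared):
                raise ValueError(
                    f"standard curve for amplicon {amp} failed QC "
                    f"(r²={fit.r_squared:.4f})"
                )

    def delta(amp: tuple[int, int]) -> tuple[float, float]:
        d = by_amp[amp]
        if "IP" not in d or "input" not in d:
            raise ValueError(f"amplicon {amp} missing IP or input measurements")
        dct = float(np.mean(d["IP"]) - np.mean(d["input"]))
        sd = float(np.sqrt(np.var(d["IP"], ddof=1) + np.var(d["input"], ddof=1))) if (
            len(d["IP"]) > 1 and len(d["input"]) > 1
        ) else float("nan")
        return dct, sd

    dct_control, _ = delta(control)
    points = []
    for amp in sorted(by_amp):
        dct, sd = delta(amp)
        ddct = dct - dct_control
        points.append(EnrichmentPoint(amp, dct, ddct, -ddct, sd))
    return points


def plot_profile(points: list[EnrichmentPoint], path, title: str = "") -> None:
    """Write the enrichment profile (log2 fold vs genomic position) to an
    image file, one marker per amplicon midpoint."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [(p.amplicon[0] + p.amplicon[1]) / 2 / 1e6 for p in points]
    ys = [p.log_fold for p in points]
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(xs, ys, "o-", ms=4)
    ax.axhline(0.0, lw=0.8, color="grey")
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(r"$-\Delta\Delta$Ct (log$_2$ fold)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
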