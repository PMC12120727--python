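"""Saturation-binding analysis: specific MFI and one-site Kd fitting.

The assay measures mean fluorescence intensity (MFI) of cells incubated
with a fluorophore-labelled aptamer over a concentration series.  The
specific signal is the test aptamer's MFI minus a control sequence's
MFI at the same concentration.  Specific MFI is fitted to the one-site
saturation model

    Y = Bmax * X / (Kd + X)

where X is aptamer concentration (nM), Kd the dissociation constant
(nM; half-saturating concentration), and Bmax the maximal specific
signal.  Each replicate is fitted separately and the Kd is summarized
as mean +/- sample SD, matching how such assays are usually reported;
a pooled fit over all replicates is available as an option.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ASSAY_CONCENTRATIONS_NM",
    "BindingCurve",
    "KdFit",
    "one_site",
    "specific_mfi",
    "fit_one_site",
    "summarize_replicates",
    "read_binding_csv",
    "write_fit_report",
]

#: Concentration grid (nM) of the standard assay.
ASSAY_CONCENTRATIONS_NM = (0.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0, 600.0)


def one_site(x, bmax, kd):
    """One-site saturation model Y = Bmax*X/(Kd+X)."""
    x = np.asarray(x, dtype=float)
    return bmax * x / (kd + x)


def specific_mfi(sample, control):
    """Elementwise sample - control MFI.  Negative values are preserved:
    clamping at zero would bias the fitted Kd upward."""
    sample = np.asarray(sample, dtype=float)
    control = np.asarray(control, dtype=float)
    if sample.shape != control.shape:
        raise ValueError("sample and control MFI must have matching shapes")
    return sample - control


@dataclass
class BindingCurve:
    """Concentration series with per-replicate sample and control MFI.

    ``mfi_sample`` and ``mfi_control`` are (n_replicates, n_points)
    arrays matched to ``concentrations``.
    """

    concentrations: np.ndarray
    mfi_sample: np.ndarray
    mfi_control: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.mfi_sample = np.atleast_2d(np.asarray(self.mfi_sample, dtype=float))
        self.mfi_control = np.atleast_2d(np.asarray(self.mfi_control, dtype=float))
        if self.mfi_sample.shape != self.mfi_control.shape:
            raise ValueError("sample and control MFI must have matching shapes")
        if self.mfi_sample.shape[1] != self.concentrations.size:
            raise ValueError("MFI columns must match the concentration grid")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        sorted_x = np.sort(self.concentrations)
        if np.any(np.diff(sorted_x) <= 0):
            raise ValueError("concentrations must be distinct")

    @property
    def n_replicates(self) -> int:
        return self.mfi_sample.shape[0]

    @property
    def specific(self) -> np.ndarray:
        return specific_mfi(self.mfi_sample, self.mfi_control)


@dataclass
class KdFit:
    """Fitted one-site parameters with a replicate summary.

    ``kd``/``bmax`` are the headline estimates (mean over replicate fits,
    or the pooled fit when fitted pooled); ``kd_sd`` is the sample SD
    (n-1 denominator) over replicates, absent for a single replicate.
    """

    kd: float
    bmax: float
    residual_ss: float
    per_replicate: list[tuple[float, float]] = field(default_factory=list)
    kd_sd: float | None = None
    pooled: bool = False

    @property
    def summary(self) -> str:
        if self.kd_sd is None:
            return f"Kd = {self.kd:.2f} nM"
        return f"Kd = {self.kd:.2f} +/- {self.kd_sd:.2f} nM (n = {len(self.per_replicate)})"


def _fit_single(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    if not np.any(y != 0):
        raise ValueError("no binding signal: all specific MFI are zero")
    bmax0 = float(np.max(y))
    if bmax0 <= 0:
        bmax0 = float(np.max(np.abs(y))) or 1.0
    positive = x[x > 0]
    if positive.size < 3:
        raise ValueError("need at least 3 distinct positive concentrations")
    kd0 = float(positive[np.argmin(np.abs(y[x > 0] - bmax0 / 2))])
    try:
        popt, _ = curve_fit(
            one_site,
            x,
            y,
            p0=(bmax0, kd0),
            bounds=((1e-12, 1e-12), (np.inf, np.inf)),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError(
            f"one-site fit did not converge (p0 Bmax={bmax0:.3g}, Kd={kd0:.3g}): {exc}"
        ) from exc
    bmax, kd = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - one_site(x, bmax, kd)) ** 2))
    return kd, bmax, rss


def fit_one_site(curve: BindingCurve, pooled: bool = False) -> KdFit:
    """Least-squares fit of the one-site model to specific MFI.

    Initialization: Bmax0 = max(Y); Kd0 = the concentration whose signal
    is nearest Bmax0/2.  Both parameters are bounded positive.  By
    default each replicate is fitted separately and Kd is reported as
    the replicate mean with sample SD; ``pooled=True`` fits all points
    jointly instead.
    """
    x = curve.concentrations
    spec = curve.specific
    if pooled:
        x_all = np.tile(x, curve.n_replicates)
        kd, bmax, rss = _fit_single(x_all, spec.ravel())
        return KdFit(kd=kd, bmax=bmax, residual_ss=rss,
                     per_replicate=[(kd, bmax)], kd_sd=None, pooled=True)
    fits = [_fit_single(x, spec[r]) for r in range(curve.n_replicates)]
    kds = [f[0] for f in fits]
    bmaxs = [f[1] for f in fits]
    mean_kd, sd_kd = summarize_replicates(kds)
    return KdFit(
        kd=mean_kd,
        bmax=float(np.mean(bmaxs)),
        residual_ss=float(sum(f[2] for f in fits)),
        per_replicate=[(f[0], f[1]) for f in fits],
        kd_sd=sd_kd,
    )


def summarize_replicates(kds) -> tuple[float, float | None]:
    """Mean and sample SD (n-1) of per-replicate Kd estimates; SD is
    None for a single replicate."""
    kds = list(map(float, kds))
    if not kds:
        raise ValueError("no replicates")
    mean = sum(kds) / len(kds)
    if len(kds) < 2:
        return mean, None
    var = sum((k - mean) ** 2 for k in kds) / (len(kds) - 1)
    return mean, math.sqrt(var)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_binding_csv(path: str | Path, label: str = "") -> BindingCurve:
    """Load a CSV with columns concentration_nM, replicate, mfi_sample,
    mfi_control into a :class:`BindingCurve`."""
    df = pd.read_csv(path)
    required = {"concentration_nM", "replicate", "mfi_sample", "mfi_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    pivot_s = df.pivot_table(index="replicate", columns="concentration_nM",
                             values="mfi_sample", sort=True)
    pivot_c = df.pivot_table(index="replicate", columns="concentration_nM",
                             values="mfi_control", sort=True)
    if pivot_s.isna().any().any() or pivot_c.isna().any().any():
        raise ValueError(f"{path}: incomplete replicate x concentration grid")
    return BindingCurve(
        concentrations=pivot_s.columns.to_numpy(dtype=float),
        mfi_sample=pivot_s.to_numpy(dtype=float),
        mfi_control=pivot_c.to_numpy(dtype=float),
        label=label or Path(path).stem,
    )


def write_fit_report(fit: KdFit, path: str | Path, label: str = "") -> None:
    """JSON fit report (kd, bmax, per-replicate estimates, summary)."""
    payload = {
        "label": label,
        "kd_nM": fit.kd,
        "kd_sd_nM": fit.kd_sd,
        "bmax": fit.bmax,
        "residual_ss": fit.residual_ss,
        "pooled": fit.pooled,
        "n_replicates": len(fit.per_replicate),
        "per_replicate": [{"kd_nM": k, "bmax": b} for k, b in fit.per_replicate],
        "summary": fit.summary,
    }
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2)
        handle.write("\n")
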