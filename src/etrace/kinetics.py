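"""Enzyme kinetics: traces -> initial velocities -> Michaelis-Menten fit.

The quantification chain mirrors a standard spectrophotometric workflow:

1. An absorbance time course (product formation raising the signal, or
   substrate consumption lowering it) is converted to an initial
   velocity v0 by ordinary least squares over the early, linear part of
   the trace: v0 = |slope| x conversion, where `conversion` is the
   molar-per-absorbance-unit factor (1 / (extinction coefficient x path
   length)).
2. Velocities across substrate concentrations are fitted to the
   Michaelis-Menten model v = Vmax S / (Km + S) by nonlinear least
   squares (positivity-bounded trust-region, Hanes-Woolf start values).
3. kcat = Vmax / [E]0 and the catalytic efficiency kcat/Km follow as
   exact arithmetic identities.

Replicate experiments are fitted one by one, then summarised as
mean +/- SD of the parameters across replicates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, KineticsInputError

Direction = Literal["increase", "decrease"]


@dataclass
class KineticTrace:
    """One absorbance time course with its assay metadata.

    times are seconds (strictly increasing), signal is in absorbance
    units; ``conversion`` (M per AU) converts signal changes to
    concentration changes; ``direction`` says whether the tracked
    species accumulates or is consumed.
    """

    times: np.ndarray
    signal: np.ndarray
    substrate_conc: float  # M
    enzyme_conc: float  # M, [E]0
    conversion: float  # M per absorbance unit
    direction: Direction = "increase"
    label: str = ""
    replicate: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.signal.shape:
            raise KineticsInputError("times and signal must be 1-D and equal length")
        if len(self.times) < 3:
            raise KineticsInputError("a trace needs at least 3 time points")
        if np.any(np.diff(self.times) <= 0):
            raise KineticsInputError("times must be strictly increasing")
        if self.conversion <= 0:
            raise KineticsInputError(f"conversion must be > 0, got {self.conversion}")
        if self.enzyme_conc <= 0:
            raise KineticsInputError(f"enzyme_conc must be > 0, got {self.enzyme_conc}")
        if self.substrate_conc <= 0:
            raise KineticsInputError(
                f"substrate_conc must be > 0, got {self.substrate_conc}"
            )
        if self.direction not in ("increase", "decrease"):
            raise KineticsInputError(f"unknown direction {self.direction!r}")


@dataclass
class RateEstimate:
    """Initial velocity from the linear early phase of one trace."""

    v0: float  # M/s, >= 0
    window: tuple[int, int]  # (start, end) indices, end exclusive
    r_squared: float
    substrate_conc: float  # M
    slope_se: float = math.nan  # M/s standard error of v0
    label: str = ""
    replicate: int = 0


@dataclass
class MMFit:
    """Michaelis-Menten parameters for one enzyme/substrate pair."""

    vmax: float  # M/s
    km: float  # M
    kcat: float  # 1/s, = vmax / enzyme_conc
    kcat_over_km: float  # 1/(s M), = kcat / km
    se_vmax: float
    se_km: float
    n_points: int
    enzyme_conc: float
    label: str = ""
    replicate: int = 0


def initial_velocity(
    trace: KineticTrace,
    window_frac: float = 0.2,
    window: Optional[tuple[int, int]] = None,
    r2_floor: float = 0.0,
) -> RateEstimate:
    """Initial velocity by OLS on the earliest part of the trace.

    Default window is the earliest 20% of points (minimum 3); an
    explicit (start, end) index window overrides it. A low r-squared
    only warns (via the returned value), it never fails.
    """
    n = len(trace.times)
    if window is None:
        k = max(3, int(math.ceil(window_frac * n)))
        window = (0, min(k, n))
    start, end = window
    if not (0 <= start < end <= n) or end - start < 3:
        raise KineticsInputError(f"window {window} must contain >= 3 points")
    t = trace.times[start:end]
    y = trace.signal[start:end]
    slope, _, _, _, slope_se = _ols_line(t, y)
    r2 = _r_squared(t, y, slope)
    v0 = abs(slope) * trace.conversion
    if r2 < r2_floor:
        import warnings

        warnings.warn(
            f"initial-velocity fit r^2={r2:.3f} below floor {r2_floor}", stacklevel=2
        )
    return RateEstimate(
        v0=v0,
        window=(start, end),
        r_squared=r2,
        substrate_conc=trace.substrate_conc,
        slope_se=slope_se * trace.conversion,
        label=trace.label,
        replicate=trace.replicate,
    )


def _ols_line(t, y):
    if np.ptp(y) == 0.0:
        # flat signal: zero slope, exact fit of a constant
        return 0.0, float(y[0]), 1.0, 0.0, 0.0
    return stats.linregress(t, y)


def _r_squared(t, y, slope) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0
    intercept = y.mean() - slope * t.mean()
    resid = y - (intercept + slope * t)
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def michaelis_menten(s, vmax, km):
    """v = Vmax * S / (Km + S)."""
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def _hanes_woolf_init(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Start values from the Hanes-Woolf linearisation S/v = S/Vmax + Km/Vmax."""
    ok = v > 0
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(s[ok], s[ok] / v[ok], 1)
        if slope > 0 and intercept > 0:
            return 1.0 / slope, intercept / slope
    # fall back to a coarse guess when the linearisation is degenerate
    return float(v.max()) * 1.2 if v.max() > 0 else 1e-9, float(np.median(s))


def fit_michaelis_menten(
    rates: Sequence[RateEstimate], enzyme_conc: float
) -> MMFit:
    """Nonlinear least-squares Michaelis-Menten fit of initial velocities.

    Requires >= 4 distinct substrate concentrations. Parameters are
    constrained positive; standard errors come from the local curvature
    (covariance of the converged least-squares solution); kcat and
    kcat/Km are derived exactly from the fitted Vmax and Km.
    """
    if enzyme_conc <= 0:
        raise KineticsInputError(f"enzyme_conc must be > 0, got {enzyme_conc}")
    s = np.array([r.substrate_conc for r in rates], dtype=float)
    v = np.array([r.v0 for r in rates], dtype=float)
    if np.any(v < 0):
        raise KineticsInputError("initial velocities must be >= 0")
    if len(np.unique(s)) < 4:
        raise KineticsInputError(
            f"need >= 4 distinct substrate concentrations, got {len(np.unique(s))}"
        )
    vmax0, km0 = _hanes_woolf_init(s, v)
    try:
        popt, pcov = optimize.curve_fit(
            michaelis_menten,
            s,
            v,
            p0=[vmax0, km0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(
            f"Michaelis-Menten fit did not converge: {exc}", init=(vmax0, km0)
        ) from exc
    vmax, km = float(popt[0]), float(popt[1])
    se = np.sqrt(np.diag(pcov))
    kcat, kcat_over_km = catalytic_constants(vmax, km, enzyme_conc)
    return MMFit(
        vmax=vmax,
        km=km,
        kcat=kcat,
        kcat_over_km=kcat_over_km,
        se_vmax=float(se[0]),
        se_km=float(se[1]),
        n_points=len(s),
        enzyme_conc=enzyme_conc,
        label=rates[0].label if rates else "",
        replicate=rates[0].replicate if rates else 0,
    )


def catalytic_constants(
    vmax: float, km: float, enzyme_conc: float
) -> tuple[float, float]:
    """kcat = Vmax/[E]0 and kcat/Km, both exact arithmetic identities."""
    if vmax <= 0 or km <= 0 or enzyme_conc <= 0:
        raise KineticsInputError(
            "vmax, km and enzyme_conc must all be > 0 "
            f"(got {vmax}, {km}, {enzyme_conc})"
        )
    kcat = vmax / enzyme_conc
    return kcat, kcat / km


def round_sig(x: float, digits: int = 3) -> float:
    """Round to `digits` significant figures (reporting helper)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


# ---------------------------------------------------------------------------
# Replicate handling and file I/O


def fit_replicates(
    rates: Sequence[RateEstimate], enzyme_conc: float
) -> list[MMFit]:
    """One Michaelis-Menten fit per replicate id, in replicate order."""
    reps = sorted({r.replicate for r in rates})
    return [
        fit_michaelis_menten([r for r in rates if r.replicate == rep], enzyme_conc)
        for rep in reps
    ]


def summarize_fits(fits: Sequence[MMFit]) -> dict:
    """Mean +/- SD of Km, kcat and kcat/Km across replicate fits."""
    if not fits:
        raise KineticsInputError("no fits to summarize")

    def _ms(values):
        a = np.asarray(values, dtype=float)
        return float(a.mean()), float(a.std(ddof=1)) if len(a) > 1 else 0.0

    km_m, km_s = _ms([f.km for f in fits])
    kcat_m, kcat_s = _ms([f.kcat for f in fits])
    eff_m, eff_s = _ms([f.kcat_over_km for f in fits])
    return {
        "label": fits[0].label,
        "n_replicates": len(fits),
        "km_M_mean": km_m,
        "km_M_sd": km_s,
        "kcat_per_s_mean": kcat_m,
        "kcat_per_s_sd": kcat_s,
        "kcat_over_km_mean": eff_m,
        "kcat_over_km_sd": eff_s,
    }


def read_trace(csv_path, sidecar_path=None) -> KineticTrace:
    """Read one trace CSV (columns time_s, signal) plus its JSON sidecar.

    The sidecar (default: same stem, .json) must define substrate_conc_M,
    enzyme_conc_M, conversion_M_per_AU and direction; label and
    replicate are optional.
    """
    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    df = pd.read_csv(csv_path)
    for col in ("time_s", "signal"):
        if col not in df.columns:
            raise KineticsInputError(f"{csv_path}: missing column {col!r}")
    try:
        meta = json.loads(Path(sidecar_path).read_text())
    except FileNotFoundError:
        raise KineticsInputError(f"missing sidecar {sidecar_path}") from None
    except json.JSONDecodeError as exc:
        raise KineticsInputError(f"bad sidecar {sidecar_path}: {exc}") from exc
    try:
        return KineticTrace(
            times=df["time_s"].to_numpy(),
            signal=df["signal"].to_numpy(),
            substrate_conc=float(meta["substrate_conc_M"]),
            enzyme_conc=float(meta["enzyme_conc_M"]),
            conversion=float(meta["conversion_M_per_AU"]),
            direction=meta.get("direction", "increase"),
            label=str(meta.get("label", "")),
            replicate=int(meta.get("replicate", 0)),
        )
    except KeyError as exc:
        raise KineticsInputError(f"{sidecar_path}: missing field {exc}") from exc


def write_trace(trace: KineticTrace, csv_path, sidecar_path=None) -> None:
    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    pd.DataFrame({"time_s": trace.times, "signal": trace.signal}).to_csv(
        csv_path, index=False
    )
    meta = {
        "substrate_conc_M": trace.substrate_conc,
        "enzyme_conc_M": trace.enzyme_conc,
        "conversion_M_per_AU": trace.conversion,
        "direction": trace.direction,
        "label": trace.label,
        "replicate": trace.replicate,
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def rates_to_frame(rates: Sequence[RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [r.label for r in rates],
            "replicate": [r.replicate for r in rates],
            "substrate_conc_M": [r.substrate_conc for r in rates],
            "v0_M_per_s": [r.v0 for r in rates],
            "r_squared": [r.r_squared for r in rates],
            "window_start": [r.window[0] for r in rates],
            "window_end": [r.window[1] for r in rates],
        }
    )


def fits_to_frame(fits: Sequence[MMFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [f.label for f in fits],
            "replicate": [f.replicate for f in fits],
            "vmax_M_per_s": [f.vmax for f in fits],
            "km_M": [f.km for f in fits],
            "kcat_per_s": [f.kcat for f in fits],
            "kcat_over_km_per_s_per_M": [f.kcat_over_km for f in fits],
            "se_vmax": [f.se_vmax for f in fits],
            "se_km": [f.se_km for f in fits],
            "n_points": [f.n_points for f in fits],
            "enzyme_conc_M": [f.enzyme_conc for f in fits],
        }
    )
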