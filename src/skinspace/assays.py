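"""Standalone calculators for the bench-assay quantifications.

Comet-assay DNA damage (Tail DNA % and Olive Tail Moment), mitochondrial
membrane potential (TMRM fluorescence minus the FCCP-depolarized
baseline), vesicle loading efficiency, logistic replicative-lifespan
fitting with the 95%-of-saturation time, and mitochondrial skeleton
length classification.

Note on the Olive Tail Moment: the classical definition multiplies the
tail DNA fraction by the tail-centre distance; here it is computed as
Tail DNA (%) divided by the tail moment length, which is the form this
pipeline standardizes on. Callers expecting the multiplicative
convention should not use this function unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np
from scipy.optimize import curve_fit

MITO_FRAGMENTED_MAX_UM = 3.0   # lengths below this are fragmented
MITO_ELONGATED_MIN_UM = 8.0    # lengths at or above this are elongated
MITO_CLASSES = ("fragmented", "intermediate", "elongated")


def tail_dna_percent(tail_intensity: float, cell_intensity: float) -> float:
    """Tail DNA (%) = 100 x tail intensity / whole-cell intensity."""
    if cell_intensity <= 0:
        raise ValueError("cell intensity must be > 0")
    if tail_intensity < 0 or tail_intensity > cell_intensity:
        raise ValueError("tail intensity must lie in [0, cell intensity]")
    # ratio first: keeps the result <= 100 even when tail == cell
    return 100.0 * (tail_intensity / cell_intensity)


def olive_tail_moment(tail_dna_pct: float, tail_moment_length: float) -> float:
    """Olive Tail Moment = Tail DNA (%) / tail moment length (see module note)."""
    if tail_moment_length <= 0:
        raise ValueError("tail moment length must be > 0")
    if tail_dna_pct < 0:
        raise ValueError("tail DNA percent must be >= 0")
    return tail_dna_pct / tail_moment_length


def delta_psi_m(f_treatment: float, f_fccp: float) -> float:
    """End-point membrane potential: F_treatment - F_FCCP (a.u.)."""
    return f_treatment - f_fccp


def loading_efficiency(total_nad: float, free_nad_in_filtrate: float) -> float:
    """Percent of cargo retained: 100 x (total - free in filtrate) / total."""
    if total_nad <= 0:
        raise ValueError("total amount must be > 0")
    if not (0 <= free_nad_in_filtrate <= total_nad):
        raise ValueError("free amount must lie in [0, total]")
    return 100.0 * (total_nad - free_nad_in_filtrate) / total_nad


@dataclass
class LogisticFit:
    """Logistic growth fit N(t) = K / (1 + exp(-r (t - t0)))."""

    K: float
    r: float
    t0: float

    @property
    def t95(self) -> float:
        """Day at 95% of saturation: t0 + ln(19)/r."""
        return self.t0 + log(19.0) / self.r

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.K / (1.0 + np.exp(-self.r * (t - self.t0)))


def _logistic(t, K, r, t0):
    return K / (1.0 + np.exp(-r * (t - t0)))


def fit_logistic(time_points, cell_counts) -> LogisticFit:
    """Least-squares logistic growth fit.

    Initialization: K from 105% of the observed maximum, t0 from the
    half-maximum crossing, r from the early-phase log-linear slope.
    """
    t = np.asarray(time_points, dtype=float)
    n = np.asarray(cell_counts, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    if (np.diff(t) <= 0).any():
        raise ValueError("time points must be strictly increasing")
    if (n <= 0).any():
        raise ValueError("cell counts must be > 0")
    if np.allclose(n, n[0]):
        raise ValueError("degenerate flat series; logistic fit undefined")

    k0 = n.max() * 1.05
    t0_0 = float(t[np.argmin(np.abs(n - k0 / 2.0))])
    early = n < k0 / 2.0
    if early.sum() >= 2:
        slope = np.polyfit(t[early], np.log(n[early]), 1)[0]
        r0 = max(slope, 1.0 / (t[-1] - t[0]))
    else:
        r0 = 1.0 / (t[-1] - t[0])

    try:
        popt, _ = curve_fit(
            _logistic,
            t,
            n,
            p0=[k0, r0, t0_0],
            bounds=([0.0, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"logistic fit did not converge: {err}") from err
    return LogisticFit(K=float(popt[0]), r=float(popt[1]), t0=float(popt[2]))


def classify_mito_length(skeleton_length_um: float) -> str:
    """Fragmented < 3 μm; intermediate [3, 8) μm; elongated >= 8 μm."""
    if skeleton_length_um < 0:
        raise ValueError("length must be >= 0")
    if skeleton_length_um < MITO_FRAGMENTED_MAX_UM:
        return "fragmented"
    if skeleton_length_um < MITO_ELONGATED_MIN_UM:
        return "intermediate"
    return "elongated"


def mito_fractions(lengths) -> dict[str, float]:
    """Class proportions over (fragmented, intermediate, elongated)."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("empty length list")
    classes = [classify_mito_length(v) for v in lengths]
    return {c: classes.count(c) / len(classes) for c in MITO_CLASSES}
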