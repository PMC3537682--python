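"""Quantitative classifiers for the qualitative spatial-response behaviours.

The motifs' behaviours are described qualitatively (the response "mirrors" or
"opposes" the signal, shows a "spatial switch", oscillates "irregularly" or
"synchronously"), so this module makes each of them an explicit, tunable
classifier: circular correlation for alignment, a two-means plateau split for
spatial switching, a step-doubling index for adaptation, peak detection for
per-node periods, and a phase-portrait occupancy measure separating
quasiperiodic (densely filled) from synchronized (closed-curve) dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from .domain import SpatialDomain
from .errors import ShapeError
from .motifs import MotifModel
from .simulate import homogeneous_steady

__all__ = [
    "DiagnosticsReport",
    "classify_alignment",
    "adaptation_index",
    "detect_spatial_switch",
    "oscillation_analysis",
]

#: Default classifier thresholds (config-exposed; the source behaviours are
#: qualitative, so the operationalization must be explicit).
CORRELATION_THRESHOLD = 0.5
FLATNESS_THRESHOLD = 0.01
GAP_THRESHOLD = 0.5
AMPLITUDE_THRESHOLD = 1e-3
SYNCHRONY_PERIOD_TOL = 1e-3
MIN_PEAK_SEPARATION = 5
OCCUPANCY_BINS = 50


@dataclass
class SwitchRecord:
    detected: bool
    edges: List[int] = field(default_factory=list)
    plateau_levels: Tuple[float, float] = (0.0, 0.0)
    gap: float = 0.0


@dataclass
class OscillationRecord:
    oscillating: np.ndarray  # boolean per node
    period: np.ndarray  # per node (nan where not oscillating)
    amplitude: np.ndarray  # peak-to-peak per node
    synchrony_index: float
    quasiperiodicity_occupancy: float
    node_pair: Optional[Tuple[int, int]] = None


@dataclass
class DiagnosticsReport:
    alignment: Optional[str] = None  # co | counter | flat
    correlation: Optional[float] = None
    contrast: Optional[float] = None
    baseline: Optional[float] = None
    adaptation: Optional[float] = None
    switch: Optional[SwitchRecord] = None
    oscillation: Optional[OscillationRecord] = None

    def to_dict(self) -> Dict:
        out: Dict = {
            "alignment": self.alignment,
            "correlation": self.correlation,
            "contrast": self.contrast,
            "baseline": self.baseline,
            "adaptation": self.adaptation,
        }
        if self.switch is not None:
            out["switch"] = {
                "detected": self.switch.detected,
                "edges": list(map(int, self.switch.edges)),
                "plateau_levels": list(self.switch.plateau_levels),
                "gap": self.switch.gap,
            }
        if self.oscillation is not None:
            osc = self.oscillation
            out["oscillation"] = {
                "oscillating_nodes": int(np.sum(osc.oscillating)),
                "synchrony_index": osc.synchrony_index,
                "quasiperiodicity_occupancy": osc.quasiperiodicity_occupancy,
                "node_pair": list(osc.node_pair) if osc.node_pair else None,
            }
        return out


def classify_alignment(response, signal, domain: SpatialDomain) -> Tuple[str, float]:
    """Co-/counter-alignment of a response with the signal.

    Mean-removed circular correlation rho over the nodes; "co" for rho > 0.5,
    "counter" for rho < -0.5, "flat" when the response contrast is below 1%
    of its mean or |rho| <= 0.5 (and by definition for zero-variance signals).
    """
    r = domain.check_field(response)
    s = domain.check_field(signal)
    contrast = float(np.max(r) - np.min(r))
    mean = float(np.mean(np.abs(r)))
    if mean > 0 and contrast / mean < FLATNESS_THRESHOLD:
        return "flat", 0.0
    sv = s - s.mean()
    rv = r - r.mean()
    denom = np.sqrt(np.sum(sv**2) * np.sum(rv**2))
    if denom == 0:
        return "flat", 0.0
    rho = float(np.sum(sv * rv) / denom)
    if rho > CORRELATION_THRESHOLD:
        return "co", rho
    if rho < -CORRELATION_THRESHOLD:
        return "counter", rho
    return "flat", rho


def response_contrast(response) -> float:
    """Spatial contrast max - min of a steady profile."""
    r = np.asarray(response, dtype=float)
    return float(np.max(r) - np.min(r))


def response_baseline(response, signal) -> float:
    """Response level at the node where the signal is smallest."""
    r = np.asarray(response, dtype=float)
    s = np.asarray(signal, dtype=float)
    return float(r[int(np.argmin(s))])


def adaptation_index(
    model: MotifModel,
    S_level: float,
    factor: float = 2.0,
    response_species: Optional[str] = None,
) -> float:
    """Adaptation of the homogeneous steady response to a step-doubled signal.

    index = 1 - |R2 - R1| / max(R1, R2) in [0, 1]; 1 is perfect adaptation
    (the steady response is insensitive to the homogeneous signal level).
    """
    if factor <= 1:
        raise ValueError("factor must exceed 1")
    if response_species is None:
        response_species = "R*" if "R*" in model.species else model.species[0]
    j = model.species.index(response_species)
    r1 = float(homogeneous_steady(model, S_level)[j])
    r2 = float(homogeneous_steady(model, factor * S_level)[j])
    top = max(r1, r2)
    if top <= 0:
        return 1.0
    return 1.0 - abs(r2 - r1) / top


def _two_means_split(values: np.ndarray) -> Tuple[float, np.ndarray]:
    """Exact 1-D two-means: best threshold over sorted values.

    Returns (gap between cluster extremes, boolean upper-cluster mask).
    """
    order = np.sort(values)
    n = order.size
    best_cost, best_split = np.inf, 1
    prefix = np.concatenate([[0.0], np.cumsum(order)])
    prefix2 = np.concatenate([[0.0], np.cumsum(order**2)])
    for split in range(1, n):
        cost = 0.0
        for lo, hi in ((0, split), (split, n)):
            m = hi - lo
            s1 = prefix[hi] - prefix[lo]
            s2 = prefix2[hi] - prefix2[lo]
            cost += s2 - s1 * s1 / m
        if cost < best_cost:
            best_cost, best_split = cost, split
    threshold = 0.5 * (order[best_split - 1] + order[best_split])
    upper = values > threshold
    gap = float(order[best_split] - order[best_split - 1])
    return gap, upper


def detect_spatial_switch(
    response, domain: SpatialDomain, gap_threshold: float = GAP_THRESHOLD
) -> SwitchRecord:
    """Detect a two-plateau (spatially switched) steady profile.

    The node values are split into two clusters (exact 1-D two-means); a
    switch is flagged when the inter-cluster gap exceeds ``gap_threshold``
    times the overall range and each plateau spans at least 3 nodes. Edge
    positions are the node indices where the cluster label changes.
    """
    r = domain.check_field(response)
    rng = float(np.max(r) - np.min(r))
    if rng <= 0:
        return SwitchRecord(detected=False)
    _, upper = _two_means_split(r)
    n_up = int(np.sum(upper))
    levels = (
        float(np.mean(r[~upper])) if n_up < r.size else float(np.min(r)),
        float(np.mean(r[upper])) if n_up > 0 else float(np.max(r)),
    )
    if 0 < n_up < r.size:
        # trimmed cluster gap: a steep front leaves a node or two mid-level,
        # so compare the clusters' 10th/90th percentiles instead of extremes
        # (a smooth profile's clusters abut, keeping the trimmed gap small)
        gap = max(
            0.0,
            float(np.percentile(r[upper], 10.0) - np.percentile(r[~upper], 90.0)),
        )
    else:
        gap = 0.0
    detected = (
        gap > gap_threshold * rng and n_up >= 3 and (r.size - n_up) >= 3
    )
    edges: List[int] = []
    if detected:
        lab = upper.astype(int)
        changes = np.nonzero(lab != np.roll(lab, 1))[0]
        edges = [int(i) for i in changes]
    return SwitchRecord(detected=detected, edges=edges, plateau_levels=levels, gap=gap)


def oscillation_analysis(
    times,
    trajectory,
    transient_fraction: float = 0.5,
    min_periods: int = 10,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
    node_pair: Optional[Tuple[int, int]] = None,
) -> OscillationRecord:
    """Per-node oscillation metrics from a (n_times, n_nodes) trajectory.

    A node oscillates when its post-transient peak-to-peak amplitude exceeds
    ``amplitude_threshold`` times its mean level. Periods are mean inter-peak
    intervals (peak detection on the de-trended series, minimum separation 5
    samples). synchrony_index = 1 - (max period - min period)/mean period over
    oscillating nodes, floored at 0. quasiperiodicity_occupancy is the filled
    fraction of a 50x50 binning of the phase portrait (u_i(t), u_{i+1}(t)) for
    an adjacent node pair inside the oscillating region: closed curves give
    low occupancy, dense (torus-filling) trajectories high occupancy.
    """
    t = np.asarray(times, dtype=float)
    u = np.asarray(trajectory, dtype=float)
    if u.ndim != 2 or u.shape[0] != t.size:
        raise ShapeError("trajectory must be (n_times, n_nodes) matching times")
    i0 = int(np.floor(transient_fraction * t.size))
    t_post, u_post = t[i0:], u[i0:]
    if t_post.size < 4 * MIN_PEAK_SEPARATION:
        raise ShapeError("trajectory too short after transient discard")

    n_nodes = u.shape[1]
    oscillating = np.zeros(n_nodes, dtype=bool)
    period = np.full(n_nodes, np.nan)
    amplitude = np.zeros(n_nodes)
    for j in range(n_nodes):
        series = u_post[:, j]
        amp = float(np.max(series) - np.min(series))
        amplitude[j] = amp
        level = float(np.mean(np.abs(series)))
        if level <= 0 or amp <= amplitude_threshold * level:
            continue
        detrended = series - np.polyval(np.polyfit(t_post, series, 1), t_post)
        peaks, _ = find_peaks(detrended, distance=MIN_PEAK_SEPARATION,
                              prominence=0.1 * amp)
        if peaks.size < 2:
            continue
        if peaks.size < min_periods + 1:
            # oscillating but under-sampled; period still estimated
            pass
        oscillating[j] = True
        period[j] = float(np.mean(np.diff(t_post[peaks])))

    osc_periods = period[oscillating]
    if osc_periods.size == 0:
        synchrony = 0.0
    else:
        mean_t = float(np.mean(osc_periods))
        synchrony = max(
            0.0, 1.0 - (float(np.max(osc_periods)) - float(np.min(osc_periods))) / mean_t
        )

    occupancy = 0.0
    pair = node_pair
    if pair is None and np.sum(oscillating) >= 2:
        # innermost adjacent oscillating pair (interior of the oscillating set)
        idx = np.nonzero(oscillating)[0]
        adjacent = idx[:-1][np.diff(idx) == 1]
        if adjacent.size:
            mid = adjacent[adjacent.size // 2]
            pair = (int(mid), int(mid) + 1)
    if pair is not None:
        a = u_post[:, pair[0]]
        b = u_post[:, pair[1]]
        occupancy = _phase_occupancy(a, b)
    return OscillationRecord(
        oscillating=oscillating, period=period, amplitude=amplitude,
        synchrony_index=synchrony, quasiperiodicity_occupancy=occupancy,
        node_pair=pair,
    )


def _phase_occupancy(a: np.ndarray, b: np.ndarray, bins: int = OCCUPANCY_BINS) -> float:
    def scaled(x):
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)
    H, _, _ = np.histogram2d(scaled(a), scaled(b), bins=bins, range=[[0, 1], [0, 1]])
    return float(np.count_nonzero(H)) / (bins * bins)
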