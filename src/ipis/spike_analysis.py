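"""Spike-level pipeline: population E/I state detection, IPIS and excitatory
center-spike extraction, partner-cell classification, jitter-surrogate
cross-correlograms, spike SNR, and state-conditioned firing rates.

Conventions shared by the module: intervals are half-open ``[start, end)`` in
seconds; lag-0 coincidences are counted in the first positive-lag bin; jitter
surrogates resample every reference time uniformly within +-``jitter_s``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .synthetic_data import E, I, SpikeTrain, StateIntervals

__all__ = [
    "IpisEvent",
    "Correlogram",
    "PartnerMap",
    "detect_states_from_spikes",
    "extract_ipis",
    "extract_e_center_spikes",
    "cross_correlogram",
    "classify_partner_cells",
    "classify_spikes",
    "spike_snr",
    "firing_rate_by_state",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IpisEvent:
    """One inhibitory-period isolated spike."""

    unit_id: str
    spike_time_s: float
    interval_index: int  # index into the StateIntervals tuple (an I interval)


@dataclass(frozen=True)
class Correlogram:
    lags_s: np.ndarray  # bin centers
    counts: np.ndarray  # observed pair counts per bin
    rate_norm: np.ndarray  # coincidences per reference event per second
    null_band: np.ndarray  # (2, n_bins): pointwise [2.5, 97.5] percentiles
    null_mean: np.ndarray
    clusters: tuple[tuple[float, float, float, float], ...]  # (lag_lo, lag_hi, mass, p)
    n_ref: int
    bin_s: float
    low_n_warning: bool = False

    def significant_clusters(self, alpha: float = 0.05) -> list[tuple[float, float, float, float]]:
        return [c for c in self.clusters if c[3] < alpha]


@dataclass(frozen=True)
class PartnerMap:
    pairs: tuple[tuple[str, str, float, float], ...]  # (bnst, nac, peak_lag_s, p)
    partner_bnst_units: frozenset[str]
    partner_windows: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# E/I state detection from population firing
# ---------------------------------------------------------------------------

def detect_states_from_spikes(
    spike_trains: Sequence[SpikeTrain],
    duration_s: float | None = None,
    bin_s: float = 0.01,
    low_pct: float = 20.0,
    high_pct: float = 60.0,
    min_dur_s: float = 0.1,
    smooth_s: float = 0.02,
) -> StateIntervals:
    """Label inhibitory / excitatory network states from the pooled,
    Gaussian-smoothed population rate.

    Bins where the rate is at or below the ``low_pct`` percentile seed I
    intervals, bins at or above the ``high_pct`` percentile seed E intervals;
    each core run is then extended outward to the crossing of the mid-level
    between the two thresholds, and runs shorter than ``min_dur_s`` are
    discarded.  Remaining time stays unlabeled.
    """
    if len(spike_trains) < 2:
        raise ValueError("state detection needs at least 2 units")
    all_times = np.concatenate([t.times for t in spike_trains]) if spike_trains else np.empty(0)
    if all_times.size == 0:
        raise ValueError("empty spike set")
    if duration_s is None:
        duration_s = float(all_times.max()) + bin_s
    n_bins = int(np.ceil(duration_s / bin_s))
    counts, _ = np.histogram(all_times, bins=n_bins, range=(0.0, n_bins * bin_s))
    rate = gaussian_filter1d(counts.astype(float) / bin_s, sigma=smooth_s / bin_s)

    lo = np.percentile(rate, low_pct)
    hi = np.percentile(rate, high_pct)
    if hi <= lo:  # all-silent or degenerate recording
        warnings.warn("degenerate population rate; labeling whole recording as I")
        return StateIntervals(((0.0, duration_s, I),), duration_s)
    mid = 0.5 * (lo + hi)

    def runs(mask: np.ndarray) -> list[tuple[int, int]]:
        d = np.diff(mask.astype(int))
        starts = list(np.where(d == 1)[0] + 1)
        ends = list(np.where(d == -1)[0] + 1)
        if mask[0]:
            starts.insert(0, 0)
        if mask[-1]:
            ends.append(mask.size)
        return list(zip(starts, ends))

    below_mid = rate <= mid
    above_mid = ~below_mid

    def extend(core: tuple[int, int], side_mask: np.ndarray) -> tuple[int, int]:
        s, e = core
        while s > 0 and side_mask[s - 1]:
            s -= 1
        while e < side_mask.size and side_mask[e]:
            e += 1
        return s, e

    # the threshold condition must persist before edge extension (half the
    # minimum duration; extension only refines boundaries), so fluctuations
    # that merely touch a threshold do not seed intervals
    min_core = max(1, int(round(0.5 * min_dur_s / bin_s)))
    candidates: list[tuple[float, float, str]] = []
    for s, e in runs(rate <= lo):
        if e - s < min_core:
            continue
        s, e = extend((s, e), below_mid)
        candidates.append((s * bin_s, min(e * bin_s, duration_s), I))
    for s, e in runs(rate >= hi):
        if e - s < min_core:
            continue
        s, e = extend((s, e), above_mid)
        candidates.append((s * bin_s, min(e * bin_s, duration_s), E))

    # drop short runs, merge duplicates produced by cores sharing one extension
    candidates = [c for c in candidates if c[1] - c[0] >= min_dur_s]
    candidates.sort()
    merged: list[tuple[float, float, str]] = []
    for c in candidates:
        if merged and c[0] < merged[-1][1] - 1e-12:
            if merged[-1][2] == c[2]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], c[1]), c[2])
            else:  # conflicting labels on the overlap: truncate at the boundary
                merged.append((merged[-1][1], c[1], c[2]))
        else:
            merged.append(c)
    merged = [c for c in merged if c[1] - c[0] >= min_dur_s]
    return StateIntervals(tuple(merged), duration_s)


# ---------------------------------------------------------------------------
# event extraction
# ---------------------------------------------------------------------------

def extract_ipis(
    spike_trains: Sequence[SpikeTrain],
    states: StateIntervals,
    k_max: int = 2,
) -> list[IpisEvent]:
    """Inhibitory-period isolated spikes: for each unit and I interval, the
    spikes are IPIS iff the unit fired between 1 and ``k_max`` times in that
    interval ("single or few action potentials")."""
    i_intervals = [
        (idx, s, e) for idx, (s, e, lab) in enumerate(states.intervals) if lab == I
    ]
    if not i_intervals:
        raise ValueError("states contain no I interval")
    events: list[IpisEvent] = []
    for train in spike_trains:
        t = train.times
        for idx, s, e in i_intervals:
            a, b = np.searchsorted(t, [s, e])
            if 1 <= b - a <= k_max:
                events.extend(
                    IpisEvent(train.unit_id, float(x), idx) for x in t[a:b]
                )
    return events


def extract_e_center_spikes(
    spike_trains: Sequence[SpikeTrain], states: StateIntervals
) -> list[IpisEvent]:
    """Per unit and E interval, the spike nearest the interval midpoint
    (ties resolved toward the earlier spike)."""
    e_intervals = [
        (idx, s, e) for idx, (s, e, lab) in enumerate(states.intervals) if lab == E
    ]
    if not e_intervals:
        raise ValueError("states contain no E interval")
    events: list[IpisEvent] = []
    for train in spike_trains:
        t = train.times
        for idx, s, e in e_intervals:
            a, b = np.searchsorted(t, [s, e])
            if b <= a:
                continue
            mid = 0.5 * (s + e)
            seg = t[a:b]
            d = np.abs(seg - mid)
            # ties (within float tolerance) resolve to the earlier spike
            k = int(np.flatnonzero(d <= d.min() + 1e-9)[0])
            events.append(IpisEvent(train.unit_id, float(seg[k]), idx))
    return events


# ---------------------------------------------------------------------------
# cross-correlogram with jitter-surrogate Monte-Carlo null
# ---------------------------------------------------------------------------

def _bin_counts(ref: np.ndarray, target: np.ndarray, edges_rel: np.ndarray) -> np.ndarray:
    """Counts of target spikes in lag bins relative to every reference event.

    Implemented as differences of searchsorted positions at shifted bin edges,
    which counts lag-0 coincidences in the first positive bin (right-open bins).
    """
    if ref.size == 0:
        return np.zeros(edges_rel.size - 1, dtype=float)
    abs_edges = ref[:, None] + edges_rel[None, :]
    pos = np.searchsorted(target, abs_edges.ravel()).reshape(abs_edges.shape)
    return np.diff(pos, axis=1).sum(axis=0).astype(float)


def _clusters_from_counts(
    counts: np.ndarray, hi: np.ndarray, ref: np.ndarray
) -> list[tuple[int, int, float]]:
    """Contiguous supra-null bins with mass = sum(counts - reference level)."""
    above = counts > hi
    out: list[tuple[int, int, float]] = []
    i = 0
    n = counts.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            out.append((i, j, float(np.sum(counts[i : j + 1] - ref[i : j + 1]))))
            i = j + 1
        else:
            i += 1
    return out


def cross_correlogram(
    ref_events: np.ndarray | Sequence[float],
    target_train: np.ndarray | SpikeTrain,
    max_lag_s: float = 0.2,
    bin_s: float = 0.005,
    n_surr: int = 1000,
    jitter_s: float = 0.2,
    seed: int | np.random.SeedSequence = 0,
) -> Correlogram:
    """Spike cross-correlogram with a jitter-surrogate Monte-Carlo null.

    The pointwise null band is the [2.5, 97.5] percentile envelope over
    ``n_surr`` surrogates in which each reference time is independently
    re-drawn uniformly within +-``jitter_s``.  Clusters of contiguous bins
    above the envelope are scored by mass (count excess over the surrogate
    mean) against the distribution of maximal surrogate cluster masses.
    """
    ref = np.sort(np.asarray(ref_events, dtype=float))
    target = target_train.times if isinstance(target_train, SpikeTrain) else np.asarray(target_train, float)
    target = np.sort(target)

    n_half = int(round(max_lag_s / bin_s))
    edges = (np.arange(2 * n_half + 1) - n_half) * bin_s
    centers = 0.5 * (edges[:-1] + edges[1:])

    low_n = ref.size < 10
    counts = _bin_counts(ref, target, edges)

    rng = np.random.default_rng(seed)
    surr = np.empty((n_surr, centers.size))
    for k in range(n_surr):
        jit = np.sort(ref + rng.uniform(-jitter_s, jitter_s, ref.size))
        surr[k] = _bin_counts(jit, target, edges)
    band = np.percentile(surr, [2.5, 97.5], axis=0)
    null_mean = surr.mean(axis=0)

    obs_clusters = _clusters_from_counts(counts, band[1], null_mean)
    # null distribution of the maximal cluster mass, using the same band
    surr_max = np.zeros(n_surr)
    for k in range(n_surr):
        cl = _clusters_from_counts(surr[k], band[1], null_mean)
        if cl:
            surr_max[k] = max(c[2] for c in cl)
    clusters = []
    for i, j, mass in obs_clusters:
        p = (1.0 + np.sum(surr_max >= mass)) / (1.0 + n_surr)
        clusters.append((float(edges[i]), float(edges[j + 1]), mass, float(p)))

    with np.errstate(invalid="ignore", divide="ignore"):
        rate_norm = counts / max(ref.size, 1) / bin_s
    return Correlogram(
        lags_s=centers,
        counts=counts,
        rate_norm=rate_norm,
        null_band=band,
        null_mean=null_mean,
        clusters=tuple(clusters),
        n_ref=int(ref.size),
        bin_s=bin_s,
        low_n_warning=low_n,
    )


# ---------------------------------------------------------------------------
# partner cells and partner spikes
# ---------------------------------------------------------------------------

def classify_partner_cells(
    bnst_trains: Sequence[SpikeTrain],
    nac_trains: Sequence[SpikeTrain],
    states: StateIntervals,
    alpha: float = 0.05,
    window_s: float = 0.05,
    k_max: int = 2,
    n_surr: int = 1000,
    min_ref: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> PartnerMap:
    """Identify partner BNST units: units whose IPIS-restricted spike times
    show a significant positive cross-correlogram cluster with some NAc unit
    within +-``window_s`` (cluster-corrected at ``alpha`` per pair).

    Pairs with fewer than ``min_ref`` IPIS reference events are not testable
    and are skipped.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(bnst_trains) * len(nac_trains)))
    ipis = extract_ipis(bnst_trains, states, k_max=k_max)
    by_unit: dict[str, list[float]] = {}
    for ev in ipis:
        by_unit.setdefault(ev.unit_id, []).append(ev.spike_time_s)

    pairs: list[tuple[str, str, float, float]] = []
    windows: dict[tuple[str, str], tuple[float, float]] = {}
    for b in bnst_trains:
        ref = np.asarray(by_unit.get(b.unit_id, []), float)
        for n in nac_trains:
            child = next(children)
            if ref.size < min_ref:
                continue
            cg = cross_correlogram(
                ref, n, max_lag_s=2 * window_s, n_surr=n_surr, seed=child
            )
            best = None
            for lo, hi, mass, p in cg.clusters:
                if p < alpha and lo < window_s and hi > -window_s:
                    if best is None or mass > best[2]:
                        best = (lo, hi, mass, p)
            if best is not None:
                lo, hi, mass, p = best
                in_cluster = (cg.lags_s >= lo) & (cg.lags_s < hi)
                peak_lag = float(cg.lags_s[in_cluster][np.argmax(cg.counts[in_cluster])])
                w = (max(lo, -window_s), min(hi, window_s))
                pairs.append((b.unit_id, n.unit_id, peak_lag, p))
                windows[(b.unit_id, n.unit_id)] = w
    return PartnerMap(
        pairs=tuple(pairs),
        partner_bnst_units=frozenset(p[0] for p in pairs),
        partner_windows=windows,
    )


def classify_spikes(
    partner_map: PartnerMap,
    bnst_trains: Sequence[SpikeTrain],
    nac_trains: Sequence[SpikeTrain],
) -> dict[str, np.ndarray]:
    """Label every BNST spike ``partner_spike`` (True) or ``other_spike``.

    A spike of unit *b* at time *t* is a partner spike iff, for some partner
    pair (b, n) with significant lag window (w0, w1), an NAc spike of unit *n*
    falls in ``[t + w0, t + w1)``.  Uses spike timestamps only.
    """
    nac_by_unit = {t.unit_id: t.times for t in nac_trains}
    labels: dict[str, np.ndarray] = {}
    for b in bnst_trains:
        lab = np.zeros(b.times.size, dtype=bool)
        for (bu, nu), (w0, w1) in partner_map.partner_windows.items():
            if bu != b.unit_id:
                continue
            nt = nac_by_unit.get(nu)
            if nt is None or nt.size == 0:
                continue
            lo = np.searchsorted(nt, b.times + w0)
            hi = np.searchsorted(nt, b.times + w1)
            lab |= hi > lo
        labels[b.unit_id] = lab
    return labels


# ---------------------------------------------------------------------------
# spike SNR around events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnrResult:
    t_s: np.ndarray
    snr: np.ndarray
    control_band: np.ndarray  # (2, n_bins)
    control_mean: np.ndarray
    epsilon_hz: float
    n_events: int


def spike_snr(
    events: np.ndarray | Sequence[float],
    labeled_trains: Sequence[SpikeTrain],
    labels: dict[str, np.ndarray],
    duration_s: float,
    win_s: float = 0.025,
    span_s: float = 0.5,
    n_shift: int = 200,
    epsilon_hz: float = 0.1,
    seed: int | np.random.SeedSequence = 0,
) -> SnrResult:
    """Peri-event SNR time course: (partner-spike rate + eps) / (other-spike
    rate + eps) in ``win_s`` bins over +-``span_s`` around the events, averaged
    over events, with a circularly time-shifted Monte-Carlo control."""
    ev = np.sort(np.asarray(events, float))
    if ev.size == 0:
        raise ValueError("no events")
    partner = np.sort(
        np.concatenate(
            [t.times[labels[t.unit_id]] for t in labeled_trains if t.unit_id in labels]
            or [np.empty(0)]
        )
    )
    other = np.sort(
        np.concatenate(
            [t.times[~labels[t.unit_id]] for t in labeled_trains if t.unit_id in labels]
            or [np.empty(0)]
        )
    )
    n_half = int(round(span_s / win_s))
    edges = (np.arange(2 * n_half + 1) - n_half) * win_s
    centers = 0.5 * (edges[:-1] + edges[1:])

    def snr_for(ev_times: np.ndarray) -> np.ndarray:
        pr = _bin_counts(ev_times, partner, edges) / ev_times.size / win_s
        orr = _bin_counts(ev_times, other, edges) / ev_times.size / win_s
        return (pr + epsilon_hz) / (orr + epsilon_hz)

    obs = snr_for(ev)
    rng = np.random.default_rng(seed)
    ctrl = np.empty((n_shift, centers.size))
    for k in range(n_shift):
        shift = rng.uniform(span_s, duration_s - span_s)
        ctrl[k] = snr_for(np.sort((ev + shift) % duration_s))
    band = np.percentile(ctrl, [2.5, 97.5], axis=0)
    return SnrResult(
        t_s=centers,
        snr=obs,
        control_band=band,
        control_mean=ctrl.mean(axis=0),
        epsilon_hz=epsilon_hz,
        n_events=int(ev.size),
    )


# ---------------------------------------------------------------------------
# state-conditioned firing rates
# ---------------------------------------------------------------------------

def firing_rate_by_state(
    spike_trains: Sequence[SpikeTrain], states: StateIntervals
) -> dict[str, dict[str, float]]:
    """Per-unit overall/E/I firing rates (spike count in labeled intervals
    divided by total labeled duration).  A state with zero labeled duration
    yields ``nan`` (undefined), never zero."""
    if len(states) == 0:
        raise ValueError("states are empty")
    dur = {lab: states.total_duration(lab) for lab in (E, I)}
    out: dict[str, dict[str, float]] = {}
    for train in spike_trains:
        t = train.times
        rates: dict[str, float] = {}
        total_count = 0
        for lab in (E, I):
            count = 0
            for s, e in states.of_label(lab):
                a, b = np.searchsorted(t, [s, e])
                count += b - a
            total_count += count
            rates[lab] = count / dur[lab] if dur[lab] > 0 else float("nan")
        labeled = dur[E] + dur[I]
        rates["overall"] = total_count / labeled if labeled > 0 else float("nan")
        out[train.unit_id] = rates
    return out
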