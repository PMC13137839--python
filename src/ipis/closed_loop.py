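"""Event-driven simulator of the four DBS paradigms.

A causal low-firing-period detector triggers stimulation according to one of
four paradigms (inhibitory-period-locked, random-delay, excitatory-period-
locked, or open-loop full-time).  Stimulation acts on the generator through a
dual mechanism: somatic BNST rates are multiplied by ``s_soma`` during pulses
(plus a short carryover), the NAc background is forced toward its inhibitory-
period statistics during pulses (axonal GABA drive), and the pathological
inhibitory-period rate gains relax toward 1 with efficacy ``e`` in proportion
to how much of each inhibitory interval was stimulated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import spike_analysis as sa
from .synthetic_data import (
    E,
    I,
    SpikeTrain,
    StateIntervals,
    SyntheticRecording,
    simulate_spikes,
)

__all__ = [
    "DbsProtocol",
    "StimSchedule",
    "DbsEffectParams",
    "DetectionResult",
    "online_detector",
    "schedule",
    "apply_dbs",
    "evaluate_paradigm",
    "PARADIGMS",
]

PARADIGMS = ("I_locked", "random_delay", "E_locked", "full_time")


@dataclass(frozen=True)
class DbsProtocol:
    paradigm: str
    pulse_dur_s: float = 0.1
    delay_range_s: tuple[float, float] = (0.5, 1.0)
    trail_win_s: float = 0.1
    low_pct: float = 20.0
    high_pct: float = 60.0
    refractory_s: float = 0.3
    baseline_s: float = 30.0
    stim_freq_hz: float = 160.0  # metadata; intra-pulse dynamics are not modeled

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.pulse_dur_s <= 0:
            raise ValueError("pulse_dur_s must be positive")


@dataclass(frozen=True)
class StimSchedule:
    intervals: tuple[tuple[float, float, str], ...]  # (start, end, trigger_type)
    triggering_event_times: tuple[float, ...]

    def windows(self) -> list[tuple[float, float]]:
        return [(s, e) for s, e, _ in self.intervals]


@dataclass(frozen=True)
class DetectionResult:
    i_onsets: np.ndarray
    e_onsets: np.ndarray
    rate_t: np.ndarray
    rate_hz: np.ndarray
    low_threshold: float
    high_threshold: float


def online_detector(
    spike_trains: Sequence[SpikeTrain],
    duration_s: float,
    trail_win_s: float = 0.1,
    low_pct: float = 20.0,
    high_pct: float = 60.0,
    refractory_s: float = 0.3,
    baseline_s: float = 30.0,
    bin_s: float = 0.01,
    confirm_bins: int = 2,
) -> DetectionResult:
    """Causal low/high-firing-period detector on the pooled spike stream.

    The population rate at time t is the spike count in the trailing window
    ``(t - trail_win_s, t]``; thresholds are the ``low_pct``/``high_pct``
    percentiles of that rate over the leading ``baseline_s`` calibration
    period.  Downward crossings below the low threshold emit I-onsets, upward
    crossings above the high threshold emit E-onsets, each with a refractory
    period.
    """
    pooled = np.sort(np.concatenate([t.times for t in spike_trains]))
    if pooled.size == 0 or pooled[pooled < baseline_s].size == 0:
        raise ValueError("baseline period contains no spikes; cannot calibrate detector")
    grid = np.arange(bin_s, duration_s + bin_s / 2, bin_s)
    hi_idx = np.searchsorted(pooled, grid, side="right")
    lo_idx = np.searchsorted(pooled, grid - trail_win_s, side="right")
    rate = (hi_idx - lo_idx) / trail_win_s

    base = rate[grid <= baseline_s]
    low_thr = float(np.percentile(base, low_pct))
    high_thr = float(np.percentile(base, high_pct))

    # a crossing fires only after persisting for confirm_bins consecutive
    # bins (costs confirm_bins x bin_s of latency, rejects rate flickers)
    i_onsets: list[float] = []
    e_onsets: list[float] = []
    last_i = last_e = -np.inf
    run_below = run_above = 0
    armed_i = armed_e = False
    for t, r in zip(grid, rate):
        run_below = run_below + 1 if r <= low_thr else 0
        run_above = run_above + 1 if r >= high_thr else 0
        if run_below == 0:
            armed_i = True
        if run_above == 0:
            armed_e = True
        if armed_i and run_below >= confirm_bins and t - last_i >= refractory_s:
            i_onsets.append(t)
            last_i = t
            armed_i = False
        if armed_e and run_above >= confirm_bins and t - last_e >= refractory_s:
            e_onsets.append(t)
            last_e = t
            armed_e = False
    return DetectionResult(
        i_onsets=np.asarray(i_onsets),
        e_onsets=np.asarray(e_onsets),
        rate_t=grid,
        rate_hz=rate,
        low_threshold=low_thr,
        high_threshold=high_thr,
    )


def schedule(
    protocol: DbsProtocol,
    detections: DetectionResult | None,
    duration_s: float,
    seed: int | np.random.SeedSequence = 0,
) -> StimSchedule:
    """Stimulation schedule for a paradigm.

    I_locked: one pulse at every detected I-onset.  random_delay: pulse at
    I-onset + U(delay_range).  E_locked: pulse at the first detected E-onset
    after each I-onset.  full_time: a single interval covering the recording.
    Overlapping pulses are merged.
    """
    if protocol.paradigm == "full_time":
        return StimSchedule(((0.0, duration_s, "full_time"),), ())
    if detections is None:
        raise ValueError("closed-loop paradigms need detector output")
    rng = np.random.default_rng(seed)
    pulses: list[tuple[float, float, str]] = []
    triggers: list[float] = []
    i_onsets = detections.i_onsets
    if protocol.paradigm == "I_locked":
        starts = i_onsets
    elif protocol.paradigm == "random_delay":
        starts = i_onsets + rng.uniform(*protocol.delay_range_s, size=i_onsets.size)
    elif protocol.paradigm == "E_locked":
        e_on = detections.e_onsets
        idx = np.searchsorted(e_on, i_onsets, side="right")
        valid = idx < e_on.size
        starts = np.unique(e_on[idx[valid]])
    else:  # pragma: no cover
        raise AssertionError
    for s in np.sort(starts):
        if s >= duration_s:
            continue
        pulses.append((float(s), float(min(s + protocol.pulse_dur_s, duration_s)), protocol.paradigm))
        triggers.append(float(s))
    merged: list[tuple[float, float, str]] = []
    for p in pulses:
        if merged and p[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], p[1]), p[2])
        else:
            merged.append(p)
    return StimSchedule(tuple(merged), tuple(triggers))


@dataclass(frozen=True)
class DbsEffectParams:
    """Mechanistic stimulation-effect parameters.

    ``s_soma`` scales somatic BNST rates during stimulation; ``efficacy``
    relaxes the pathological I-state gains toward 1 in proportion to the
    cumulative stimulated-I coverage; ``carryover_s`` extends the somatic
    suppression beyond each pulse.  ``tonic_fidelity`` is the reception
    fidelity of inhibitory windows protected by *ongoing* (tonic) drive that
    began before the window: sustained GABA bombardment enforces silence but
    partially occludes the rebound-timed NAc response, so it is slightly less
    effective than a pulse locked to the window onset (phasic drive, fidelity
    1)."""

    s_soma: float = 0.1  # somatic rate multiplier during stimulation
    efficacy: float = 0.9  # relaxation of pathological I-state gains toward 1
    carryover_s: float = 0.2  # suppression outlasts each pulse by this much
    tonic_fidelity: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_soma <= 1.0 or not 0.0 <= self.efficacy <= 1.0:
            raise ValueError("s_soma and efficacy must be in [0, 1]")
        if not 0.0 <= self.tonic_fidelity <= 1.0:
            raise ValueError("tonic_fidelity must be in [0, 1]")


def _coverage_per_interval(
    states: StateIntervals, windows: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Fraction of each I interval covered by the (merged) windows."""
    i_ivs = states.of_label(I)
    cov = np.zeros(len(i_ivs))
    for k, (s, e) in enumerate(i_ivs):
        total = 0.0
        for ws, we in windows:
            total += max(0.0, min(e, we) - max(s, ws))
        cov[k] = total / (e - s)
    return cov


def apply_dbs(
    recording: SyntheticRecording,
    stim: StimSchedule,
    effect_params: DbsEffectParams | None = None,
    seed: int | None = None,
) -> SyntheticRecording:
    """Regenerate the recording's spike trains under stimulation.

    During pulses (plus carryover) BNST somatic rates are multiplied by
    ``s_soma`` and NAc background rates are forced to their I-state values
    (axonal GABA drive).  In addition, each I interval's pathological
    condition gain relaxes toward 1 by ``efficacy x covered fraction`` of that
    interval, modeling the restored inhibitory tone.
    """
    ep = effect_params or DbsEffectParams()
    for s, e, _ in stim.intervals:
        if s < 0 or e > recording.duration_s + 1e-9:
            raise ValueError("stimulation schedule extends outside the recording")
    windows = [
        (s, min(e + ep.carryover_s, recording.duration_s)) for s, e in stim.windows()
    ]
    # merge carryover-extended windows
    merged: list[tuple[float, float]] = []
    for w in sorted(windows):
        if merged and w[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], w[1]))
        else:
            merged.append(w)

    states = recording.truth_states
    cov = _coverage_per_interval(states, merged)
    i_ivs = states.of_label(I)
    total_i = sum(e - s for s, e in i_ivs) or 1.0
    # cumulative coverage drives a sustained relaxation of the pathological
    # gains toward 1 (restored inhibitory tone outlasts individual pulses)
    coverage = float(sum(c * (e - s) for c, (s, e) in zip(cov, i_ivs)) / total_i)
    cond = recording.condition
    gains = {}
    s_soma_i = {}
    for key, g in (
        ("partner", cond.i_state_rate_gain_partner),
        ("other", cond.i_state_rate_gain_other),
    ):
        g_eff = 1.0 + (g - 1.0) * (1.0 - ep.efficacy * coverage)
        gains[key] = np.full(len(i_ivs), g_eff)
        # during pulses the suppression acts on the raw pathological rate,
        # not on the already-relaxed between-pulse tone
        s_soma_i[key] = ep.s_soma * g / g_eff

    # reception fidelity: an inhibitory window transmits only if it is silent
    # from its onset.  A pulse *starting* within the detector-latency grace of
    # the onset gives phasic, rebound-timed protection (fidelity 1); drive that
    # was already running when the window began is tonic (tonic_fidelity);
    # otherwise the degraded pathological tone decides.
    onset_grace_s = 0.1
    pulses = stim.windows()
    fidelity = np.empty(len(i_ivs))
    g_partner = float(gains["partner"][0]) if len(i_ivs) else 1.0
    for k, (s, e) in enumerate(i_ivs):
        phasic = cov[k] >= 0.5 and any(
            s - 0.02 <= ws <= s + onset_grace_s for ws, we in pulses
        )
        tonic = cov[k] >= 0.5 and any(ws < s - 0.02 and we > s for ws, we in pulses)
        if phasic:
            fidelity[k] = 1.0
        elif tonic:
            fidelity[k] = ep.tonic_fidelity
        else:
            fidelity[k] = 1.0 / max(g_partner, 1.0)

    # pulses suppress somata outright; the carryover extension persists only
    # through inhibitory time (renewed excitatory drive releases the block)
    pulse_merged: list[tuple[float, float]] = []
    for w in sorted(stim.windows()):
        if pulse_merged and w[0] <= pulse_merged[-1][1]:
            pulse_merged[-1] = (pulse_merged[-1][0], max(pulse_merged[-1][1], w[1]))
        else:
            pulse_merged.append(w)
    carry_only = _interval_difference(merged, pulse_merged)

    spike_seed = recording.seed if seed is None else seed
    ss = np.random.SeedSequence((spike_seed, 0xD5))
    spikes = simulate_spikes(
        states,
        recording.neuron_specs,
        cond,
        ss,
        i_gain_per_interval=gains,
        bnst_suppression_windows=pulse_merged,
        bnst_i_only_suppression_windows=carry_only,
        s_soma=ep.s_soma,
        s_soma_i=s_soma_i,
        nac_forced_i_windows=stim.windows(),
        relay_fidelity_per_interval=fidelity,
    )
    return replace(recording, spikes=spikes)


def _interval_difference(
    a: Sequence[tuple[float, float]], b: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Merged interval set ``a`` minus merged interval set ``b``."""
    out: list[tuple[float, float]] = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
        if cur < e:
            out.append((cur, e))
    return out


# ---------------------------------------------------------------------------
# endpoint evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParadigmReport:
    rates_pre: dict[str, float]  # overall / E / I mean BNST unit rates
    rates_post: dict[str, float]
    corr_mass_pre: float  # excess IPIS-relayed coincidences per minute, |lag| <= 50 ms
    corr_mass_post: float
    snr_peak_pre: float
    snr_peak_post: float
    delta_counts: np.ndarray  # post - pre correlogram counts
    lags_s: np.ndarray

    @property
    def restoration(self) -> float:
        return self.corr_mass_post - self.corr_mass_pre


def _mean_bnst_rates(rec: SyntheticRecording) -> dict[str, float]:
    rates = sa.firing_rate_by_state(rec.trains("BNST"), rec.truth_states)
    out = {}
    for key in ("overall", E, I):
        out[key] = float(np.mean([r[key] for r in rates.values()]))
    return out


def _ipis_correlogram(
    rec: SyntheticRecording, n_surr: int, seed: int | np.random.SeedSequence
) -> tuple[sa.Correlogram, float]:
    partner_bnst = [s.unit_id for s in rec.neuron_specs if s.region == "BNST" and s.is_partner]
    partner_nac = [s.partner_id for s in rec.neuron_specs if s.region == "BNST" and s.is_partner]
    ipis = sa.extract_ipis([rec.train(u) for u in partner_bnst], rec.truth_states)
    ref = np.sort([ev.spike_time_s for ev in ipis])
    target = np.sort(np.concatenate([rec.train(u).times for u in partner_nac]))
    cg = sa.cross_correlogram(ref, target, max_lag_s=0.1, n_surr=n_surr, seed=seed)
    # communication strength: relayed coincidences in the short positive-lag
    # window, flank-subtracted (the flanks sample the same-interval baseline),
    # per minute, so it scales with how many IPIS are actually relayed
    peak = (cg.lags_s >= 0.0) & (cg.lags_s < 0.02)
    flank = ((cg.lags_s >= -0.04) & (cg.lags_s < -0.02)) | (
        (cg.lags_s >= 0.02) & (cg.lags_s < 0.04)
    )
    excess = float(cg.counts[peak].sum() - cg.counts[flank].sum() * peak.sum() / flank.sum())
    return cg, excess / rec.duration_s * 60.0


def _snr_peak(rec: SyntheticRecording, seed: int | np.random.SeedSequence) -> float:
    partner_bnst = [s.unit_id for s in rec.neuron_specs if s.region == "BNST" and s.is_partner]
    bnst = rec.trains("BNST")
    nac = rec.trains("NAc")
    pm = sa.classify_partner_cells(
        [rec.train(u) for u in partner_bnst], nac, rec.truth_states, n_surr=100, seed=seed
    )
    if not pm.pairs:
        return 1.0
    labels = sa.classify_spikes(pm, bnst, nac)
    ipis = sa.extract_ipis([rec.train(u) for u in partner_bnst], rec.truth_states)
    events = np.sort([ev.spike_time_s for ev in ipis])
    if events.size == 0:
        return 1.0
    snr = sa.spike_snr(events, bnst, labels, rec.duration_s, n_shift=100, seed=seed)
    mid = np.abs(snr.t_s) <= 0.05
    return float(snr.snr[mid].max())


def evaluate_paradigm(
    pre: SyntheticRecording,
    post: SyntheticRecording,
    n_surr: int = 1000,
    seed: int = 0,
    include_snr: bool = True,
) -> ParadigmReport:
    """Endpoint report comparing matched pre/post-DBS recordings: BNST mean
    rates by state, the IPIS-mediated partner correlogram (significant
    positive cluster mass within +-50 ms) and its post - pre difference, and
    the peri-IPIS spike-SNR peak."""
    ss = np.random.SeedSequence(seed)
    s1, s2, s3, s4 = ss.spawn(4)
    cg_pre, mass_pre = _ipis_correlogram(pre, n_surr, s1)
    cg_post, mass_post = _ipis_correlogram(post, n_surr, s2)
    return ParadigmReport(
        rates_pre=_mean_bnst_rates(pre),
        rates_post=_mean_bnst_rates(post),
        corr_mass_pre=mass_pre,
        corr_mass_post=mass_post,
        snr_peak_pre=_snr_peak(pre, s3) if include_snr else float("nan"),
        snr_peak_post=_snr_peak(post, s4) if include_snr else float("nan"),
        delta_counts=cg_post.rate_norm - cg_pre.rate_norm,
        lags_s=cg_pre.lags_s,
    )
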