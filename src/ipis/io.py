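"""Recording container I/O (HDF5), JSON pipeline configuration, and seeded
end-to-end orchestration."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from . import ei_decoder as ed
from . import lfp_features as lf
from . import spike_analysis as sa
from .synthetic_data import (
    LfpSpec,
    SpikeTrain,
    StateIntervals,
    SyntheticRecording,
    default_neuron_specs,
    simulate_recording,
)

__all__ = [
    "SCHEMA_VERSION",
    "write_recording",
    "read_recording",
    "PipelineConfig",
    "run_pipeline",
]

SCHEMA_VERSION = "1"
log = logging.getLogger("ipis")


class SchemaError(ValueError):
    """Raised when an on-disk container does not match the expected layout."""


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_recording(rec: SyntheticRecording, path: str | Path) -> None:
    """Write a recording to the HDF5 container layout:
    ``/lfp/<region>`` (float arrays, attr ``fs_hz``), ``/spikes/<unit_id>``
    (float arrays, attr ``region``), ``/truth/states`` (start/end/label),
    root attrs ``seed``, ``condition``, ``schema_version``."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = rec.seed
        f.attrs["condition"] = rec.condition.condition
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["duration_s"] = rec.duration_s
        g_lfp = f.create_group("lfp")
        for region, trace in rec.lfp.items():
            d = g_lfp.create_dataset(region, data=np.asarray(trace, np.float64))
            d.attrs["fs_hz"] = rec.fs
        g_sp = f.create_group("spikes")
        for train in rec.spikes:
            d = g_sp.create_dataset(train.unit_id, data=train.times)
            d.attrs["region"] = train.region
        g_tr = f.create_group("truth")
        ivs = rec.truth_states.intervals
        g_tr.create_dataset("start", data=np.array([s for s, _, _ in ivs]))
        g_tr.create_dataset("end", data=np.array([e for _, e, _ in ivs]))
        g_tr.create_dataset(
            "label", data=np.array([lab for _, _, lab in ivs], dtype="S1")
        )


def read_recording(path: str | Path) -> SyntheticRecording:
    """Read and validate a recording container; NaN samples or a missing
    sampling rate raise :class:`SchemaError`."""
    try:
        with h5py.File(path, "r") as f:
            for group in ("lfp", "spikes", "truth"):
                if group not in f:
                    raise SchemaError(f"missing group /{group}")
            if str(f.attrs.get("schema_version", "")) != SCHEMA_VERSION:
                raise SchemaError("unknown or missing schema_version")
            lfp = {}
            fs = None
            for region in f["lfp"]:
                d = f["lfp"][region]
                if "fs_hz" not in d.attrs:
                    raise SchemaError(f"/lfp/{region} missing fs_hz")
                fs = float(d.attrs["fs_hz"])
                arr = d[()]
                if np.any(~np.isfinite(arr)):
                    raise SchemaError(f"/lfp/{region} contains non-finite samples")
                lfp[region] = arr
            if fs is None:
                raise SchemaError("no LFP traces")
            lengths = {a.size for a in lfp.values()}
            if len(lengths) > 1:
                raise SchemaError("LFP arrays differ in length across regions")
            spikes = []
            for unit in f["spikes"]:
                d = f["spikes"][unit]
                spikes.append(SpikeTrain(unit, str(d.attrs["region"]), d[()]))
            duration = float(f.attrs["duration_s"])
            states = StateIntervals(
                tuple(
                    (float(s), float(e), lab.decode())
                    for s, e, lab in zip(
                        f["truth"]["start"][()],
                        f["truth"]["end"][()],
                        f["truth"]["label"][()],
                    )
                ),
                duration,
            )
            seed = int(f.attrs["seed"])
            condition = str(f.attrs["condition"])
    except OSError as exc:
        raise SchemaError(f"not a readable HDF5 container: {exc}") from exc
    for t in spikes:
        if t.times.size and (t.times.min() < 0 or t.times.max() >= duration):
            raise SchemaError(f"spike times of {t.unit_id} outside [0, duration)")
    from .synthetic_data import condition_spec

    return SyntheticRecording(
        lfp=lfp,
        fs=fs,
        spikes=tuple(spikes),
        truth_states=states,
        neuron_specs=default_neuron_specs(),
        lfp_spec=LfpSpec(fs=fs),
        condition=condition_spec(condition),
        seed=seed,
        duration_s=duration,
    )


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "seed",
    "schema_version",
    "condition",
    "duration_s",
    "stages",
    "out_dir",
}
_KNOWN_STAGES = {"simulate", "spikes", "lfp", "decode"}


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    condition: str = "healthy"
    duration_s: float = 60.0
    stages: tuple[str, ...] = ("simulate", "spikes", "lfp", "decode")
    out_dir: str | None = None
    schema_version: str = SCHEMA_VERSION

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        bad = set(raw.get("stages", [])) - _KNOWN_STAGES
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return json.dumps(d, indent=2)

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        """Deterministic per-stage seed derived from the global seed."""
        digest = sum(ord(c) * 31**k for k, c in enumerate(stage)) % (2**31)
        return np.random.SeedSequence((self.seed, digest))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages on one synthetic recording and return a
    JSON-serializable report (per-stage seeds recorded for reproducibility)."""
    report: dict = {"config": json.loads(config.to_json()), "stages": {}}
    rec = None
    states = None
    try:
        if "simulate" in config.stages:
            log.info("stage simulate: condition=%s duration=%ss", config.condition, config.duration_s)
            rec = simulate_recording(
                config.condition, duration_s=config.duration_s, seed=config.seed
            )
            report["stages"]["simulate"] = {
                "n_units": len(rec.spikes),
                "n_truth_intervals": len(rec.truth_states),
                "seed": config.seed,
            }
        if rec is None:
            raise ValueError("pipeline requires the simulate stage")
        if "spikes" in config.stages:
            states = sa.detect_states_from_spikes(rec.spikes, rec.duration_s)
            ipis = sa.extract_ipis(rec.spikes, rec.truth_states)
            rates = sa.firing_rate_by_state(rec.trains("BNST"), rec.truth_states)
            report["stages"]["spikes"] = {
                "n_detected_intervals": len(states),
                "n_ipis": len(ipis),
                "mean_bnst_rate_i": float(np.nanmean([r["I"] for r in rates.values()])),
                "mean_bnst_rate_e": float(np.nanmean([r["E"] for r in rates.values()])),
            }
        if "lfp" in config.stages:
            freqs, psd = lf.welch_psd(rec.lfp["BNST"], rec.fs)
            fit = lf.parameterize_spectrum(freqs, psd)
            pac_res = lf.pac(rec.lfp["BNST"], rec.lfp["NAc"], rec.fs)
            report["stages"]["lfp"] = {
                "aperiodic_exponent_bnst": fit.exponent,
                "rel_theta_bnst": lf.band_power(freqs, psd, lf.THETA_BAND, relative=True),
                "pac_mi": pac_res.mi,
                "pac_preferred_phase_deg": pac_res.preferred_phase_deg,
                "wpli_gamma": lf.wpli(rec.lfp["BNST"], rec.lfp["NAc"], rec.fs, lf.GAMMA_BAND),
            }
        if "decode" in config.stages:
            if states is None:
                states = sa.detect_states_from_spikes(rec.spikes, rec.duration_s)
            feats = lf.sliding_features(rec.lfp, rec.fs)
            labeled = ed.label_windows(feats, states)
            model = ed.train_decoder(labeled, "RF", {"n_estimators": 200}, seed=config.seed)
            rep = ed.evaluate(model)
            decoded, table = ed.decode_lfp(model, rec.lfp, rec.fs)
            wp = ed.state_conditioned_wpli(decoded, rec.lfp, rec.fs, lf.GAMMA_BAND)
            report["stages"]["decode"] = {
                "auc": rep.auc,
                "accuracy": rep.accuracy,
                "f1": rep.f1,
                "istate_incidence_pct": ed.istate_incidence(table),
                "state_conditioned_wpli": {k: float(v) for k, v in wp.items()},
            }
    except Exception as exc:
        stage = list(report["stages"])[-1] if report["stages"] else "simulate"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        if rec is not None:
            write_recording(rec, out / "recording.h5")
    return report
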