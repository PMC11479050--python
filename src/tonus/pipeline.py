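"""End-to-end orchestration: synth -> preprocess -> segment -> features ->
classify, with persisted intermediates and a run manifest.

Every stage reads only its own sub-config; the run manifest records the
config hash and seed so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import classify as clf
from . import features as feat
from . import preprocess as pre
from . import segment as seg
from . import synth

log = logging.getLogger("tonus")


class SegmentSpec(BaseModel):
    smooth_cutoff: float = 2.0
    prominence_frac: float = 0.5
    min_window_samples: int = seg.MIN_WINDOW_SAMPLES


class FeatureSpec(BaseModel):
    band: tuple[float, float] = feat.DEFAULT_BAND
    mmav_subwindows: int = 4


class RunConfig(BaseModel):
    """Full study configuration; round-trips losslessly through JSON."""

    generator: synth.GeneratorConfig = Field(default_factory=synth.GeneratorConfig)
    filter: pre.FilterSpec = Field(default_factory=pre.FilterSpec)
    segmentation: SegmentSpec = Field(default_factory=SegmentSpec)
    features: FeatureSpec = Field(default_factory=FeatureSpec)
    split: clf.SplitSpec = Field(default_factory=clf.SplitSpec)
    grids: dict[str, dict] | None = None
    apply_emd: bool = True
    out_dir: str = "tonus_run"
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = self.model_dump_json().encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def process_session(
    session: synth.RecordingSession, config: RunConfig
) -> tuple[list[seg.SignalWindow], pre.MvcReference]:
    """Preprocess and window one session (in memory)."""
    normalized, reference = pre.preprocess_movement(
        session.movement_emg,
        session.mvc,
        session.sampling_rate,
        config.filter,
        apply_emd=config.apply_emd,
    )
    marks = seg.detect_flexion_marks(
        session.movement_angle,
        session.sampling_rate,
        smooth_cutoff=config.segmentation.smooth_cutoff,
        prominence_frac=config.segmentation.prominence_frac,
    )
    windows = seg.windows_from_marks(
        session, normalized, marks, min_samples=config.segmentation.min_window_samples
    )
    return windows, reference


def cohort_feature_table(
    sessions: list[synth.RecordingSession], config: RunConfig
) -> pd.DataFrame:
    """Feature table for a whole cohort (in memory)."""
    windows: list[seg.SignalWindow] = []
    for s in sessions:
        w, _ = process_session(s, config)
        windows.extend(w)
        log.debug("subject %s: %d windows", s.subject_id, len(w))
    fs = sessions[0].sampling_rate if sessions else config.generator.sampling_rate
    return feat.build_feature_table(
        windows, fs, config.features.band, config.features.mmav_subwindows
    )


def run_all(
    config: RunConfig, *, persist_signals: bool = True
) -> tuple[clf.EvalReport, Path]:
    """Execute the full study, persisting every intermediate under
    ``config.out_dir``; returns the report and the artifact directory."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage synth: generating cohort (seed=%d)", config.generator.seed)
    sessions = synth.generate_cohort(config.generator)
    if persist_signals:
        synth.write_cohort(sessions, out / "cohort")

    log.info("stage preprocess+segment: %d sessions", len(sessions))
    windows: list[seg.SignalWindow] = []
    window_index = []
    for s in sessions:
        try:
            w, ref = process_session(s, config)
        except Exception as exc:  # noqa: BLE001 - annotate stage and subject
            raise RuntimeError(
                f"stage preprocess/segment failed for subject {s.subject_id}: {exc}"
            ) from exc
        windows.extend(w)
        for win in w:
            window_index.append(
                {
                    "subject": win.subject_id,
                    "muscle": win.muscle,
                    "repetition": win.repetition_index,
                    "n_samples": win.n,
                }
            )
    (out / "windows.json").write_text(json.dumps(window_index, indent=1))

    log.info("stage features: %d windows", len(windows))
    fs = sessions[0].sampling_rate
    table = feat.build_feature_table(
        windows, fs, config.features.band, config.features.mmav_subwindows
    )
    feat.write_feature_table(table, out / "features.csv")

    log.info("stage classify: %d rows", len(table))
    try:
        report = clf.run_study(table, config.split, config.grids)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage classify failed: {exc}") from exc

    report_d = report.to_dict()
    report_d["elapsed_s"] = round(time.time() - t0, 2)
    (out / "report.json").write_text(json.dumps(report_d, indent=1))
    for kind, r in report.models.items():
        pd.DataFrame(
            r.confusion_percent, index=list(clf.CLASS_ORDER), columns=list(clf.CLASS_ORDER)
        ).to_csv(out / f"confusion_{kind}.csv")
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "config_hash": config.config_hash(),
        "seed": config.generator.seed,
        "n_sessions": len(sessions),
        "n_windows": len(windows),
        "n_feature_rows": int(len(table)),
        "elapsed_s": report_d["elapsed_s"],
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("run complete in %.1f s; best model %s", time.time() - t0, report.best_model)
    return report, out


def make_fixture(size: str = "tiny", seed: int = 0) -> RunConfig:
    """Small, fast study configurations for tests and examples.

    ``tiny``: 2 subjects per class, 3 repetitions, short rest/MVC trials —
    completes in well under 30 s.  ``default``: the full protocol.
    """
    if size == "default":
        gen = synth.GeneratorConfig(seed=seed)
    elif size == "tiny":
        gen = synth.GeneratorConfig(
            seed=seed,
            n_repetitions=3,
            rest_duration=2.0,
            mvc_duration=1.0,
            mvc_trials=2,
            class_counts={tc: 2 for tc in synth.ToneClass},
            carrier_band=(20.0, 220.0),  # 200 Hz-wide carrier keeps EMD cheap
        )
    else:
        raise ValueError("size must be 'tiny' or 'default'")
    return RunConfig(generator=gen, split=clf.SplitSpec(seed=seed))
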