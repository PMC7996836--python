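"""End-to-end orchestration of the conditional-entropy stress-marker analysis.

The full chain is: cohort input (synthetic generation or files on disk) ->
extreme-group selection and balancing -> EEG preprocessing -> common-channel
restriction -> per-participant expected conditional-entropy profiles -> RSA
with block summary -> leave-one-out KNN classification -> permutation
importance -> channel reduction -> reduced-channel RSA and KNN -> JSON/CSV
report.  Every stochastic stage derives its randomness from the single
configured seed, so a run is fully reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import AnalysisError
from .classify import loo_knn, permutation_importance, reduce_channels
from .cohort import QuestionnaireTable, balance_groups, drop_missing, select_extremes
from .infotheory import (
    CEProfile,
    EstimatorConfig,
    expected_ce_profile,
    profiles_to_frame,
    write_profiles_csv,
)
from .io import EEGRecording, common_channels, preprocess, read_recording, reject_artifacts, restrict
from .montage import Montage
from .rsa import similarity_matrix, summarize
from .synthetic import (
    SyntheticCohortSpec,
    SyntheticEEGSpec,
    default_eeg_spec,
    generate_eeg_cohort,
    generate_questionnaires,
)

__all__ = ["PipelineConfig", "RunReport", "run", "blocks_to_series", "profile_from_blocks"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full analysis run.

    ``mode`` is ``"synthetic"`` (generate a planted cohort) or ``"files"``
    (read a manifest CSV with participant_id, group, path columns and a
    questionnaire CSV).  The estimator config drives all information
    estimates; by default surrogate testing is disabled at pipeline scale
    (every pair would need ``n_surrogates`` full re-estimates) and can be
    switched on explicitly.  ``block_mode`` controls how multi-block
    recordings are combined: ``"concatenate"`` joins detrended blocks in
    time before a single profile is computed, ``"per-block-mean"`` computes
    a profile per block and averages them.
    """

    mode: str = "synthetic"
    out_dir: str | Path = "cemarker-output"
    seed: int = 0
    cohort_spec: SyntheticCohortSpec | None = None
    eeg_spec: SyntheticEEGSpec | None = None
    manifest_path: str | Path | None = None
    questionnaire_path: str | Path | None = None
    estimator: EstimatorConfig | None = None
    knn_k: int = 3
    n_repeats: int = 30
    reduction_rule: str = "above_average"
    block_mode: str = "concatenate"
    lowcut: float = 1.0
    highcut: float = 45.0
    target_rate: float = 250.0
    skip_preprocessing: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise AnalysisError(f"unknown pipeline mode {self.mode!r}")
        if self.mode == "files":
            for name, p in (
                ("manifest_path", self.manifest_path),
                ("questionnaire_path", self.questionnaire_path),
            ):
                if p is None or not Path(p).exists():
                    raise AnalysisError(f"files mode requires an existing {name}")
        if self.block_mode not in ("concatenate", "per-block-mean"):
            raise AnalysisError(f"unknown block_mode {self.block_mode!r}")

    def resolved_estimator(self) -> EstimatorConfig:
        if self.estimator is not None:
            return self.estimator
        return EstimatorConfig(n_surrogates=0, seed=self.seed)

    def resolved_cohort_spec(self) -> SyntheticCohortSpec:
        if self.cohort_spec is not None:
            return self.cohort_spec
        return SyntheticCohortSpec(seed=self.seed)

    def resolved_eeg_spec(self) -> SyntheticEEGSpec:
        if self.eeg_spec is not None:
            return self.eeg_spec
        return default_eeg_spec(seed=self.seed + 1)


@dataclass
class RunReport:
    """Everything a run produced, JSON-serializable."""

    parameters: dict
    stage_seconds: dict
    cohort: dict
    full_rsa: dict
    full_loo: dict
    importance: dict
    reduced_channels: list
    reduced_rsa: dict | None
    reduced_loo: dict | None
    sensitivity_loo: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def write_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def blocks_to_series(blocks, mode: str = "concatenate") -> EEGRecording:
    """Join a participant's recording blocks into one series per channel.

    Blocks are individually linearly detrended, then concatenated in time.
    All blocks must agree on channels (names and order) and sampling rate.
    """
    from scipy.signal import detrend

    blocks = list(blocks)
    if not blocks:
        raise AnalysisError("blocks_to_series needs >= 1 block")
    if mode not in ("concatenate", "per-block-mean"):
        raise AnalysisError(f"unknown block mode {mode!r}")
    first = blocks[0]
    for b in blocks[1:]:
        if b.channel_names != first.channel_names:
            raise AnalysisError(
                f"{b.participant_id}: block channel set differs "
                f"({b.channel_names} vs {first.channel_names})"
            )
        if b.sampling_rate != first.sampling_rate:
            raise AnalysisError(f"{b.participant_id}: block sampling rates differ")
    if len(blocks) == 1:
        return first
    data = np.concatenate([detrend(b.data, axis=1) for b in blocks], axis=1)
    return EEGRecording(first.participant_id, first.channel_names, first.sampling_rate, data)


def profile_from_blocks(blocks, config: EstimatorConfig, mode: str = "concatenate") -> CEProfile:
    """Expected-CE profile of a participant given one or more blocks.

    ``concatenate`` computes a single profile on the joined series (maximizes
    the sample count available to the k-NN estimators); ``per-block-mean``
    computes one profile per block and averages the CE vectors (and p-values,
    by median).
    """
    blocks = list(blocks)
    if mode == "concatenate" or len(blocks) == 1:
        return expected_ce_profile(blocks_to_series(blocks, "concatenate"), config)
    profiles = [expected_ce_profile(b, config) for b in blocks]
    ce = np.mean([p.ce_values for p in profiles], axis=0)
    pv = (
        np.median([p.p_values for p in profiles], axis=0)
        if profiles[0].p_values is not None
        else None
    )
    return CEProfile(
        participant_id=profiles[0].participant_id,
        channel_names=profiles[0].channel_names,
        ce_values=ce,
        p_values=pv,
        units=config.units,
    )


def _load_files_cohort(config: PipelineConfig):
    manifest = pd.read_csv(config.manifest_path)
    required = {"participant_id", "group", "path"}
    if not required <= set(manifest.columns):
        raise AnalysisError(f"manifest must have columns {sorted(required)}")
    base = Path(config.manifest_path).parent
    table = QuestionnaireTable.from_csv(config.questionnaire_path)
    blocks: dict[str, list[EEGRecording]] = {}
    labels = {}
    for _, row in manifest.iterrows():
        pid = str(row["participant_id"])
        labels[pid] = str(row["group"])
        path = Path(row["path"])
        if not path.is_absolute():
            path = base / path
        rec = read_recording(path)
        blocks.setdefault(pid, []).append(
            EEGRecording(pid, rec.channel_names, rec.sampling_rate, rec.data)
        )
    return table, pd.Series(labels, name="group"), blocks


def run(config: PipelineConfig) -> RunReport:
    """Execute the full analysis and write all artifacts to ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    est = config.resolved_estimator()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    def tick(stage: str) -> None:
        nonlocal t0
        now = time.perf_counter()
        timings[stage] = round(now - t0, 3)
        logger.info("stage %-22s %.2fs", stage, now - t0)
        t0 = now

    # --- cohort input -----------------------------------------------------
    if config.mode == "synthetic":
        cohort_spec = config.resolved_cohort_spec()
        table, truth = generate_questionnaires(cohort_spec)
        n_dropped = 0
    else:
        table, truth, file_blocks = _load_files_cohort(config)
        table, n_dropped = drop_missing(table)
    tick("cohort_input")

    # --- extreme-group selection and balancing ----------------------------
    selection = select_extremes(table, n_excluded_missing=n_dropped)
    if not selection.high_ids or not selection.low_ids:
        raise AnalysisError(
            f"stage select_extremes: empty group (HIGH={len(selection.high_ids)}, "
            f"LOW={len(selection.low_ids)}); cannot proceed"
        )
    selection = balance_groups(table, selection)
    analysis_ids = list(selection.balanced_high_ids) + list(selection.balanced_low_ids)
    group_labels = pd.Series(
        {pid: ("HIGH" if pid in selection.balanced_high_ids else "LOW") for pid in analysis_ids},
        name="group",
    )
    (out_dir / "cohort_selection.json").write_text(
        json.dumps(selection.to_dict(), indent=2)
    )
    tick("cohort_selection")

    # --- EEG --------------------------------------------------------------
    if config.mode == "synthetic":
        eeg_spec = config.resolved_eeg_spec()
        recordings = generate_eeg_cohort(eeg_spec, group_labels)
        blocks = {rec.participant_id: [rec] for rec in recordings}
    else:
        missing = [pid for pid in analysis_ids if pid not in file_blocks]
        if missing:
            raise AnalysisError(f"stage eeg_input: no recordings for {missing}")
        blocks = {pid: file_blocks[pid] for pid in analysis_ids}
    tick("eeg_input")

    if config.skip_preprocessing:
        processed = {pid: [reject_artifacts(b) for b in bl] for pid, bl in blocks.items()}
    else:
        processed = {}
        for pid, bl in blocks.items():
            try:
                processed[pid] = [
                    reject_artifacts(
                        preprocess(
                            b,
                            lowcut=config.lowcut,
                            highcut=config.highcut,
                            target_rate=config.target_rate,
                        )
                    )
                    for b in bl
                ]
            except Exception as exc:
                raise AnalysisError(f"stage preprocess: participant {pid}: {exc}") from exc
    tick("preprocess")

    montage = common_channels([b for bl in processed.values() for b in bl])
    processed = {pid: [restrict(b, montage) for b in bl] for pid, bl in processed.items()}
    tick("common_channels")

    # --- conditional-entropy profiles -------------------------------------
    profiles = []
    for pid in analysis_ids:
        try:
            profiles.append(profile_from_blocks(processed[pid], est, config.block_mode))
        except Exception as exc:
            raise AnalysisError(f"stage ce_profiles: participant {pid}: {exc}") from exc
    write_profiles_csv(profiles, out_dir / "ce_profiles.csv")
    profiles_to_frame(profiles).to_csv(out_dir / "ce_matrix.csv")
    tick("ce_profiles")

    # --- full-channel RSA and classification ------------------------------
    matrix = similarity_matrix(profiles)
    matrix.write_csv(out_dir / "rsa_r.csv", out_dir / "rsa_p.csv")
    full_rsa = summarize(matrix, group_labels)
    full_rsa.write_json(out_dir / "rsa_summary.json")
    tick("rsa_full")

    full_loo = loo_knn(profiles, group_labels, k=config.knn_k)
    full_loo.write_json(out_dir / "loo_full.json")
    sensitivity = {
        f"k={kk}": loo_knn(profiles, group_labels, k=kk).accuracy
        for kk in (1, 5)
        if kk < len(analysis_ids) - 1
    }
    tick("loo_full")

    report_imp = permutation_importance(
        profiles, group_labels, k=config.knn_k, n_repeats=config.n_repeats, seed=config.seed
    )
    report_imp.to_frame().to_csv(out_dir / "importance.csv", index=False)
    tick("importance")

    # --- reduced-channel re-analysis --------------------------------------
    reduced_rsa = reduced_loo = None
    try:
        reduced = reduce_channels(report_imp, config.reduction_rule)
    except AnalysisError as exc:
        logger.warning("channel reduction yielded no channels: %s", exc)
        reduced = ()
    if len(reduced) >= 2:
        reduced_montage = Montage(tuple(reduced))
        reduced_profiles = []
        for prof in profiles:
            keep = [prof.channel_names.index(c) for c in reduced]
            reduced_profiles.append(
                CEProfile(
                    participant_id=prof.participant_id,
                    channel_names=tuple(reduced),
                    ce_values=prof.ce_values[keep],
                    p_values=None if prof.p_values is None else prof.p_values[keep],
                    units=prof.units,
                )
            )
        reduced_matrix = similarity_matrix(reduced_profiles)
        reduced_matrix.write_csv(out_dir / "rsa_r_reduced.csv", out_dir / "rsa_p_reduced.csv")
        reduced_rsa = summarize(reduced_matrix, group_labels)
        reduced_loo = loo_knn(reduced_profiles, group_labels, k=config.knn_k)
        reduced_loo.write_json(out_dir / "loo_reduced.json")
    tick("reduced_reanalysis")

    parameters = {
        "mode": config.mode,
        "seed": config.seed,
        "estimator": asdict(est),
        "knn_k": config.knn_k,
        "n_repeats": config.n_repeats,
        "reduction_rule": config.reduction_rule,
        "block_mode": config.block_mode,
        "montage": list(montage.channel_names),
        "n_participants": len(analysis_ids),
    }
    report = RunReport(
        parameters=parameters,
        stage_seconds=timings,
        cohort=selection.to_dict(),
        full_rsa=full_rsa.to_dict(),
        full_loo=full_loo.to_dict(),
        importance=report_imp.to_dict(),
        reduced_channels=list(reduced),
        reduced_rsa=reduced_rsa.to_dict() if reduced_rsa else None,
        reduced_loo=reduced_loo.to_dict() if reduced_loo else None,
        sensitivity_loo=sensitivity,
    )
    report.write_json(out_dir / "run_report.json")
    return report
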