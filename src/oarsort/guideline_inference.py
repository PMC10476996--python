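"""Ensemble inference: per-fold prediction, majority voting, name-based
exclusion, sorted structure copies and a per-structure report.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import rtstruct_io
from .classifier_training import EnsembleModel
from .preprocess import ClassifierSample, PreprocessConfig, assemble_sample

logger = logging.getLogger(__name__)

OTHER = "Other"

BOWEL_KEYWORDS = (
    "tuning", "help", "x_", "y_", "opt_", "dose", "match", "artefakter",
    "artifakter", "artefakt", "gtv", "ctv", "ptv", "ring", "bowelbag",
    "abdomen", "tarm", "buk", "peritoneum",
)
PELVIS_KEYWORDS = (
    "tuning", "help", "x_", "y_", "z_", "opt", "dose", "match", "artefakter",
    "artifakter", "artefakt", "gtv", "ctv", "ptv", "ring", "analcanal",
)


@dataclass(frozen=True)
class ExclusionList:
    """Profile-specific lowercase keyword fragments forcing "Other"."""

    profile: str
    keywords: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("exclusion list must be non-empty")
        if any(k != k.lower() for k in self.keywords):
            raise ValueError("exclusion keywords must be lowercase")


EXCLUSION_LISTS: dict[str, ExclusionList] = {
    "bowel": ExclusionList("bowel", BOWEL_KEYWORDS),
    "pelvis": ExclusionList("pelvis", PELVIS_KEYWORDS),
    # phantom cohorts carry pelvis-style nuisance names
    "phantom": ExclusionList("phantom", PELVIS_KEYWORDS),
}


@dataclass
class PredictionRecord:
    patient_id: str
    structure_name: str
    fold_labels: list[str]
    fold_probabilities: np.ndarray  # (n_folds, n_classes)
    voted_label: str
    final_label: str
    exclusion_fired: bool

    def __post_init__(self) -> None:
        if self.exclusion_fired and self.final_label != OTHER:
            raise ValueError("exclusion can only map to 'Other'")


def predict_folds(
    ensemble: EnsembleModel, sample: ClassifierSample
) -> tuple[list[str], np.ndarray]:
    """One (argmax label, probability vector) per fold."""
    x = sample.channels[None]
    probs = np.stack([fold.predict_proba(x)[0] for fold in ensemble.folds])
    labels = [ensemble.vocabulary[int(p.argmax())] for p in probs]
    return labels, probs


def majority_vote(
    fold_labels: list[str], fold_probabilities: np.ndarray, vocabulary
) -> str:
    """Label with most votes; ties broken by summed probability over the
    tied labels, then by vocabulary order."""
    if not fold_labels:
        raise ValueError("need at least one fold")
    votes = Counter(fold_labels)
    top = max(votes.values())
    tied = [lab for lab, v in votes.items() if v == top]
    if len(tied) == 1:
        return tied[0]
    vocabulary = list(vocabulary)
    summed = {
        lab: float(fold_probabilities[:, vocabulary.index(lab)].sum())
        for lab in tied
    }
    best = max(summed.values())
    tied = [lab for lab in tied if summed[lab] >= best - 1e-12]
    return min(tied, key=vocabulary.index)


def name_exclusion(
    voted_label: str, structure_name: str, keywords: ExclusionList
) -> tuple[str, bool]:
    """Force "Other" when the lowercased name contains any keyword."""
    lowered = structure_name.lower()
    if any(k in lowered for k in keywords.keywords):
        return OTHER, True
    return voted_label, False


def classify_structure(
    ensemble: EnsembleModel,
    sample: ClassifierSample,
    exclusion: ExclusionList | None,
) -> PredictionRecord:
    fold_labels, fold_probs = predict_folds(ensemble, sample)
    voted = majority_vote(fold_labels, fold_probs, ensemble.vocabulary)
    if exclusion is not None:
        final, fired = name_exclusion(voted, sample.structure_name, exclusion)
    else:
        final, fired = voted, False
    return PredictionRecord(
        patient_id=sample.patient_id, structure_name=sample.structure_name,
        fold_labels=fold_labels, fold_probabilities=fold_probs,
        voted_label=voted, final_label=final, exclusion_fired=fired,
    )


def classify_patients(
    ensemble: EnsembleModel,
    patients_dir: Path | str,
    preprocess_config: PreprocessConfig,
    exclusion_enabled: bool = True,
    out_dir: Path | str | None = None,
    profile: str | None = None,
    format: str = "nifti",
) -> pd.DataFrame:
    """Classify every eligible structure under ``patients_dir``.

    Writes a per-structure report (TSV) and, when ``out_dir`` is given,
    copies each structure file under ``out_dir/sorted/<final label>/``.
    Per-structure failures are logged, never abort the batch.
    """
    patients_dir = Path(patients_dir)
    profile = profile or preprocess_config.profile
    exclusion = EXCLUSION_LISTS[profile] if exclusion_enabled else None
    if exclusion is not None:
        logger.info("exclusion keywords (%s): %s", profile, exclusion.keywords)

    records: list[PredictionRecord] = []
    patient_dirs = sorted(p for p in patients_dir.iterdir() if p.is_dir())
    for pdir in patient_dirs:
        try:
            ct, sset = rtstruct_io.load_patient(pdir, format=format)
            body = rtstruct_io.find_body(sset)
        except Exception as exc:  # noqa: BLE001 — batch robustness
            logger.warning("skipping patient %s: %s", pdir.name, exc)
            continue
        for struct in sset:
            if struct.name == body.name:
                continue
            try:
                sample = assemble_sample(ct, body, struct, preprocess_config,
                                         patient_id=pdir.name)
            except Exception as exc:  # noqa: BLE001
                logger.warning("skipping structure %r of %s: %s",
                               struct.name, pdir.name, exc)
                continue
            if sample is None:
                logger.info("structure %r of %s ineligible (oversize); skipped",
                            struct.name, pdir.name)
                continue
            record = classify_structure(ensemble, sample, exclusion)
            records.append(record)
            if out_dir is not None and format == "nifti":
                rtstruct_io.write_structure_copy(
                    pdir / f"{struct.name}.nii.gz", record.final_label,
                    pdir.name, Path(out_dir) / "sorted",
                )

    frame = pd.DataFrame([
        dict(
            patient_id=r.patient_id,
            structure_name=r.structure_name,
            voted_label=r.voted_label,
            final_label=r.final_label,
            exclusion_fired=r.exclusion_fired,
            **{f"fold{i}_label": lab for i, lab in enumerate(r.fold_labels)},
            **{f"p_{c}": float(r.fold_probabilities[:, j].mean())
               for j, c in enumerate(ensemble.vocabulary)},
        )
        for r in records
    ])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / "predictions.tsv", sep="\t", index=False)
        try:
            frame.to_excel(out_dir / "predictions.xlsx", index=False)
        except Exception:  # openpyxl optional
            logger.info("spreadsheet export unavailable; TSV written")
    return frame
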