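"""Per-patient 350-entry feature vectors and the tabular dataset.

Column order is frozen: the 8 clinical variables, then the 171 pre-treatment
descriptors (``pre.*``), then the 171 post-treatment descriptors
(``post.*``).  A patient whose post-treatment lesion disappeared gets
post-features extracted from the pre-treatment lesion footprint applied to
the post image, so vectors never contain missing values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .features import FEATURE_NAMES, TOTAL_FEATURES, DescriptorVector, extract_all
from .segmentation import normalize, region_grow
from .synthetic import RESPONSE_CLASSES, ClinicalRecord, SyntheticPatient

VECTOR_LENGTH = 8 + 2 * TOTAL_FEATURES  # 350

CLINICAL_NAMES = ClinicalRecord.FIELDS
FEATURE_COLUMNS = (
    list(CLINICAL_NAMES)
    + [f"pre.{n}" for n in FEATURE_NAMES]
    + [f"post.{n}" for n in FEATURE_NAMES]
)
TABLE_COLUMNS = ["id", "label"] + FEATURE_COLUMNS

#: Raw post images whose maximum falls below this are treated as lesion-free.
LESION_DETECT_THRESHOLD = 0.15


@dataclass
class PatientSample:
    """One dataset row: 350 ordered features plus a response-class label."""

    id: str
    label: str
    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (VECTOR_LENGTH,):
            raise DataError(
                f"patient vector must have {VECTOR_LENGTH} entries, got {self.features.shape}"
            )
        if not np.isfinite(self.features).all():
            bad = FEATURE_COLUMNS[int(np.argmax(~np.isfinite(self.features)))]
            raise DataError(f"non-finite feature {bad!r} for patient {self.id}")
        if self.label not in RESPONSE_CLASSES:
            raise DataError(f"unknown response class {self.label!r}")


def assemble(
    patient_id: str,
    clinical: ClinicalRecord,
    pre: DescriptorVector,
    post: DescriptorVector,
    label: str,
) -> PatientSample:
    """Concatenate clinical | pre | post into a 350-entry sample."""
    features = np.concatenate([clinical.as_vector(), pre.values, post.values])
    return PatientSample(id=patient_id, label=label, features=features)


def extract_patient(
    patient: SyntheticPatient,
    threshold_fraction: float = 0.40,
    n_levels: int = 16,
    detect_threshold: float = LESION_DETECT_THRESHOLD,
) -> PatientSample:
    """Run segmentation + feature extraction on one patient.

    The pre image is segmented by region growing from its maximum.  If the
    raw post image has no pixel above ``detect_threshold`` the lesion is
    considered absent and the pre-treatment mask is reused as the post
    footprint; otherwise the post image is segmented independently.
    """
    pre_norm = normalize(patient.pre_image.pixels, modality=patient.pre_image.modality)
    pre_mask = region_grow(pre_norm, "auto", threshold_fraction)
    pre_vec = extract_all(pre_norm, pre_mask, n_levels=n_levels)

    post_raw = patient.post_image.pixels
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero post images are expected
        post_norm = normalize(post_raw, modality=patient.post_image.modality)
    if float(post_raw.max()) < detect_threshold:
        post_mask = pre_mask  # lesion absent: reuse the pre-treatment footprint
    else:
        post_mask = region_grow(post_norm, "auto", threshold_fraction)
    post_vec = extract_all(post_norm, post_mask, n_levels=n_levels)
    return assemble(patient.id, patient.clinical, pre_vec, post_vec, patient.label)


def build_dataset(patients: list[SyntheticPatient], **kwargs) -> list[PatientSample]:
    """Extract every patient of a cohort into dataset rows."""
    return [extract_patient(p, **kwargs) for p in patients]


def to_frame(samples: list[PatientSample]) -> pd.DataFrame:
    """Samples -> DataFrame with the frozen column order (float features)."""
    features = (
        np.vstack([s.features for s in samples])
        if samples
        else np.empty((0, VECTOR_LENGTH))
    )
    frame = pd.DataFrame(features, columns=FEATURE_COLUMNS)
    frame.insert(0, "label", [s.label for s in samples])
    frame.insert(0, "id", [s.id for s in samples])
    return frame


def from_frame(frame: pd.DataFrame) -> list[PatientSample]:
    if list(frame.columns) != TABLE_COLUMNS:
        raise DataError(
            f"dataset has {len(frame.columns)} columns, expected {len(TABLE_COLUMNS)} "
            "with the documented names/order"
        )
    return [
        PatientSample(id=str(row[0]), label=str(row[1]), features=np.asarray(row[2:], dtype=float))
        for row in frame.itertuples(index=False)
    ]


def write_table(samples: list[PatientSample], path) -> None:
    """Write samples as UTF-8 CSV (full float precision, mandatory header)."""
    # %.17g preserves every float64 bit, so read(write(x)) == x exactly
    to_frame(samples).to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> list[PatientSample]:
    """Read a dataset CSV written by :func:`write_table`.

    Round-trips exactly: ``read_table(write_table(x)) == x`` including
    column order and labels.
    """
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"malformed dataset CSV {path}: {exc}") from exc
    return from_frame(frame)


def feature_matrix(samples: list[PatientSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into (X, y) arrays for the learning stages."""
    if not samples:
        return np.empty((0, VECTOR_LENGTH)), np.empty((0,), dtype=object)
    X = np.vstack([s.features for s in samples])
    y = np.array([s.label for s in samples], dtype=object)
    return X, y
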