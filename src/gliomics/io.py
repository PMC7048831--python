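"""Case and cohort I/O for multimodal glioma MRI studies.

Each case consists of four co-registered, skull-stripped, 1 mm isotropic MRI
volumes (T1, T1Gd, T2, FLAIR), a tumor sub-region segmentation using the
BraTS label convention (1 = necrosis / non-enhancing tumor, 2 = peritumoral
edema, 4 = enhancing tumor), an optional explicit brain mask, per-case
molecular labels (MGMT methylation, IDH mutation, 1p/19q co-deletion, ATRX,
TERT) and optional survival follow-up.

Volumes and masks are exchanged as NIfTI files through :mod:`nibabel`; the
cohort label table is a CSV with one row per case.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

RAW_MODALITIES = ("T1", "T1Gd", "T2", "FLAIR")
MAP_MODALITIES = ("PTPSA", "MBM", "HE")
TARGETS = ("MGMT", "IDH", "CODEL", "ATRX", "TERT")

#: BraTS segmentation labels.
LABEL_MAP = {0: "background", 1: "NCR", 2: "ED", 4: "ET"}
VALID_LABELS = frozenset(LABEL_MAP)

POSITIVE_TOKENS = frozenset({"positive", "pos", "1", "mutant", "methylated", "codel", "yes", "true"})
NEGATIVE_TOKENS = frozenset({"negative", "neg", "0", "wt", "wildtype", "unmethylated", "non-codel", "no", "false"})
MISSING_TOKENS = frozenset({"", "na", "nan", "missing", "none", "unknown"})


class FormatError(ValueError):
    """Malformed input: unknown segmentation label, bad label token, duplicates."""


class StructuralError(ValueError):
    """Structurally inconsistent input: e.g. modality shape mismatch."""


@dataclass
class VolumeImage:
    """A 3D scalar field with isotropic millimetre spacing and a modality tag."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = "T1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 8:
            raise StructuralError(
                f"volume must be 3D with every dimension >= 8, got shape {self.data.shape}"
            )
        if any(s <= 0 for s in self.spacing):
            raise StructuralError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class SegmentationMask:
    """Integer tumor sub-region labels on the BraTS convention {0, 1, 2, 4}."""

    labels: np.ndarray
    label_map: dict = field(default_factory=lambda: dict(LABEL_MAP))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise FormatError("segmentation mask must be integer-valued")
            self.labels = as_int
        present = set(np.unique(self.labels).tolist())
        bad = present - VALID_LABELS
        if bad:
            raise FormatError(f"unknown segmentation label(s) {sorted(bad)}; expected subset of {{0,1,2,4}}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape


@dataclass
class CaseRecord:
    """One study case: images, masks, molecular labels, survival follow-up."""

    case_id: str
    images: dict[str, VolumeImage]
    mask: SegmentationMask
    brain_mask: np.ndarray | None = None
    labels: dict[str, str] = field(default_factory=dict)
    survival_months: float | None = None
    event: int | None = None

    def __post_init__(self) -> None:
        shapes = {m: im.shape for m, im in self.images.items()}
        shapes["mask"] = self.mask.shape
        if len(set(shapes.values())) != 1:
            raise StructuralError(f"all volumes of a case must share one shape, got {shapes}")
        if self.brain_mask is None:
            # Skull-stripped inputs make the nonzero support of T1 an exact brain mask.
            ref = self.images.get("T1") or next(iter(self.images.values()))
            self.brain_mask = ref.data != 0
        else:
            self.brain_mask = np.asarray(self.brain_mask) != 0
            if self.brain_mask.shape != self.mask.shape:
                raise StructuralError("brain mask shape differs from case volumes")
        if not np.any(self.mask.labels):
            raise StructuralError(f"case {self.case_id!r} has no tumor voxels")


@dataclass
class Cohort:
    """An ordered case collection plus its label table (rows aligned to cases)."""

    cases: list[CaseRecord]
    label_table: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate case_id in cohort")
        if list(self.label_table["case_id"]) != ids:
            raise StructuralError("label table row order must match case order")

    def __len__(self) -> int:
        return len(self.cases)


# ---------------------------------------------------------------------------
# region masks


def derive_region_masks(mask: SegmentationMask) -> dict[str, np.ndarray]:
    """Binary masks for WT (whole tumor), ED, ET and NCR.

    ED/ET/NCR are disjoint by construction and their union is WT; an absent
    sub-region yields an all-zero mask.
    """
    lab = mask.labels
    return {
        "WT": np.isin(lab, (1, 2, 4)),
        "NCR": lab == 1,
        "ED": lab == 2,
        "ET": lab == 4,
    }


# ---------------------------------------------------------------------------
# NIfTI case I/O


def _nifti_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def read_case(
    case_id: str,
    image_paths: dict[str, str | os.PathLike],
    mask_path: str | os.PathLike,
    brain_mask_path: str | os.PathLike | None = None,
    labels: dict[str, str] | None = None,
    survival_months: float | None = None,
    event: int | None = None,
) -> CaseRecord:
    """Load one case from NIfTI files and validate shapes and labels."""
    images = {}
    for modality, path in image_paths.items():
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        images[modality] = VolumeImage(np.asarray(img.dataobj, dtype=np.float64), spacing, modality)
    mask_img = nib.load(str(mask_path))
    mask = SegmentationMask(np.asarray(mask_img.dataobj).round().astype(np.int64))
    brain = None
    if brain_mask_path is not None:
        brain = np.asarray(nib.load(str(brain_mask_path)).dataobj) != 0
    return CaseRecord(case_id, images, mask, brain, labels or {}, survival_months, event)


def write_case(case: CaseRecord, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a case's volumes and masks to ``out_dir`` as NIfTI; return the paths."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for modality, im in case.images.items():
        p = os.path.join(out_dir, f"{case.case_id}_{modality}.nii.gz")
        nib.save(nib.Nifti1Image(im.data.astype(np.float32), _nifti_affine(im.spacing)), p)
        paths[modality] = p
    p = os.path.join(out_dir, f"{case.case_id}_seg.nii.gz")
    nib.save(nib.Nifti1Image(case.mask.labels.astype(np.int16), _nifti_affine((1, 1, 1))), p)
    paths["mask"] = p
    p = os.path.join(out_dir, f"{case.case_id}_brainmask.nii.gz")
    nib.save(nib.Nifti1Image(case.brain_mask.astype(np.int16), _nifti_affine((1, 1, 1))), p)
    paths["brain_mask"] = p
    return paths


# ---------------------------------------------------------------------------
# cohort label table


def parse_label_token(token) -> str:
    """Normalize a molecular-status token to positive / negative / missing."""
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return "missing"
    s = str(token).strip().lower()
    if s in POSITIVE_TOKENS:
        return "positive"
    if s in NEGATIVE_TOKENS:
        return "negative"
    if s in MISSING_TOKENS:
        return "missing"
    raise FormatError(f"unparseable molecular label token {token!r}")


def load_cohort_table(path: str | os.PathLike) -> pd.DataFrame:
    """Load and normalize a cohort CSV (case_id, one column per target, survival).

    Molecular columns are mapped onto {positive, negative, missing}; duplicate
    case ids or unknown tokens raise :class:`FormatError`. An empty table is
    returned as-is.
    """
    df = pd.read_csv(path, dtype={"case_id": str})
    if df.empty and "case_id" not in df.columns:
        return pd.DataFrame(columns=["case_id"])
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise FormatError(f"duplicate case_id(s) in cohort table: {dupes}")
    for col in df.columns:
        if col in TARGETS:
            df[col] = df[col].map(parse_label_token)
    return df


def target_counts(table: pd.DataFrame, target: str) -> dict[str, int]:
    """Per-target positive/negative/missing counts; they sum to the cohort size."""
    if target not in table.columns:
        return {"positive": 0, "negative": 0, "missing": len(table)}
    counts = table[target].value_counts().to_dict()
    return {k: int(counts.get(k, 0)) for k in ("positive", "negative", "missing")}


def reference_label_table() -> pd.DataFrame:
    """A synthetic 108-case label table reproducing the published TCGA-LGG
    molecular label distributions.

    The study cohort of 108 pre-operative low-grade gliomas has IDH 85
    mutant / 23 wild-type, 1p/19q 27 co-deleted / 81 non-co-deleted (all 27
    co-deletions among IDH mutants), ATRX 43/65, TERT 46/62 and MGMT 91
    methylated / 14 unmethylated with 3 cases unlabeled.  Labels here are
    assigned deterministically in case order (the last 3 cases carry the
    missing MGMT labels by convention); the table is a stand-in fixture, not
    patient data.
    """
    n = 108
    ids = [f"LGG-{i:03d}" for i in range(1, n + 1)]
    df = pd.DataFrame({"case_id": ids})

    def fill(positives: int, total: int = n) -> list[str]:
        return ["positive"] * positives + ["negative"] * (total - positives)

    df["IDH"] = fill(85)
    # co-deletion occurs only within the IDH-mutant block
    df["CODEL"] = fill(27, 85) + ["negative"] * 23
    df["ATRX"] = fill(43)
    df["TERT"] = fill(46)
    mgmt = fill(91, 105) + ["missing"] * 3
    df["MGMT"] = mgmt
    return df


def three_class_idh_codel(table: pd.DataFrame) -> pd.Series:
    """Collapse IDH and 1p/19q status into the three WHO molecular subtypes.

    Returns per-case classes ``IDHwt``, ``IDHmut-codel``, ``IDHmut-noncodel``
    (missing if either constituent label is missing).
    """
    def classify(row):
        idh, codel = row["IDH"], row["CODEL"]
        if idh == "missing" or codel == "missing":
            return "missing"
        if idh == "negative":
            return "IDHwt"
        return "IDHmut-codel" if codel == "positive" else "IDHmut-noncodel"

    return table.apply(classify, axis=1)
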