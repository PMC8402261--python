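"""Label taxonomy, sample manifests, and participant-level train/test splitting.

The posture taxonomy has two granularities: a fine 7-class level
(supine, prone with the head turned left or right, log left/right,
fetal left/right) and a coarse 4-class level (supine, prone, left and
right side-lying).  The coarse label is always *derived* from the fine
label — log and fetal merge into side-lying, the two prone head
orientations pool into prone — and is never stored independently.

Splitting is by participant, never by sample: a person contributes
frames to exactly one of the train/test sets, so evaluation is
subject-disjoint and cannot leak body shape across the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrityError, LabelError, ManifestFormatError

__all__ = [
    "FinePosture",
    "CoarsePosture",
    "BLANKET_ORDER",
    "Sample",
    "Manifest",
    "coarse_from_fine",
    "split_participants",
    "assign_split",
    "read_manifest",
    "write_manifest",
]


class FinePosture(IntEnum):
    """The 7 recumbent postures, coded in protocol order."""

    supine = 0
    prone_head_left = 1
    prone_head_right = 2
    log_left = 3
    log_right = 4
    fetal_left = 5
    fetal_right = 6


class CoarsePosture(IntEnum):
    """The 4 standard postures used for coarse-grained classification."""

    supine = 0
    prone = 1
    side_left = 2
    side_right = 3


#: Canonical ordering of blanket conditions, thickest first.  Fusion-pair
#: enumeration and all stratified reports iterate in this order.
BLANKET_ORDER: tuple[str, ...] = ("thick", "medium", "thin", "none")

_COARSE_MAP: dict[FinePosture, CoarsePosture] = {
    FinePosture.supine: CoarsePosture.supine,
    FinePosture.prone_head_left: CoarsePosture.prone,
    FinePosture.prone_head_right: CoarsePosture.prone,
    FinePosture.log_left: CoarsePosture.side_left,
    FinePosture.fetal_left: CoarsePosture.side_left,
    FinePosture.log_right: CoarsePosture.side_right,
    FinePosture.fetal_right: CoarsePosture.side_right,
}


def coarse_from_fine(fine: FinePosture | int) -> CoarsePosture:
    """Map a fine posture to its coarse class.

    Log and fetal variants merge into the corresponding side-lying
    class; the two prone head orientations pool into prone; supine maps
    to itself.
    """
    try:
        fine = FinePosture(fine)
    except ValueError as exc:
        raise LabelError(f"unknown fine posture: {fine!r}") from exc
    return _COARSE_MAP[fine]


def coarse_codes_from_fine(fine_codes: np.ndarray) -> np.ndarray:
    """Vectorized :func:`coarse_from_fine` on an integer code array."""
    lut = np.array([int(_COARSE_MAP[FinePosture(i)]) for i in range(7)])
    fine_codes = np.asarray(fine_codes)
    if fine_codes.size and (fine_codes.min() < 0 or fine_codes.max() > 6):
        raise LabelError("fine posture codes must lie in 0..6")
    return lut[fine_codes]


@dataclass(frozen=True)
class Sample:
    """One labeled depth frame."""

    sample_id: str
    participant_id: str
    fine_label: FinePosture
    blanket: str
    split: str = "train"
    path: str = ""

    @property
    def coarse_label(self) -> CoarsePosture:
        return coarse_from_fine(self.fine_label)

    def __post_init__(self):
        if self.split not in ("train", "test"):
            raise ManifestFormatError(f"unknown split {self.split!r}")


@dataclass
class Manifest:
    """Ordered collection of samples plus provenance metadata."""

    samples: list[Sample] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ManifestFormatError("duplicate sample_ids in manifest")
        triples = [(s.participant_id, s.fine_label, s.blanket) for s in self.samples]
        if len(set(triples)) != len(triples):
            raise IntegrityError(
                "a (participant, posture, blanket) triple appears more than once"
            )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.participant_id, None)
        return list(seen)

    def subset(self, split: str | None = None, blankets: set[str] | None = None) -> "Manifest":
        kept = [
            s
            for s in self.samples
            if (split is None or s.split == split)
            and (blankets is None or s.blanket in blankets)
        ]
        return Manifest(samples=kept, metadata=dict(self.metadata))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "participant_id": [s.participant_id for s in self.samples],
                "fine_label": [s.fine_label.name for s in self.samples],
                "coarse_label": [s.coarse_label.name for s in self.samples],
                "blanket": [s.blanket for s in self.samples],
                "split": [s.split for s in self.samples],
                "path": [s.path for s in self.samples],
            }
        )


def split_participants(
    participant_ids: list[str], n_train: int, n_test: int, seed: int
) -> dict[str, str]:
    """Randomly assign whole participants to train or test.

    ``n_train + n_test`` must equal the number of participants.  The
    assignment is a function of the seed only, so a rerun reproduces it.
    """
    ids = list(participant_ids)
    if n_train + n_test != len(ids):
        raise ManifestFormatError(
            f"n_train ({n_train}) + n_test ({n_test}) != {len(ids)} participants"
        )
    if n_train < 0 or n_test < 0:
        raise ManifestFormatError("split sizes must be non-negative")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {}
    for rank, idx in enumerate(order):
        assignment[ids[idx]] = "train" if rank < n_train else "test"
    return assignment


def assign_split(manifest: Manifest, assignment: dict[str, str]) -> Manifest:
    """Return a manifest with each sample carrying its participant's split."""
    samples = []
    for s in manifest.samples:
        if s.participant_id not in assignment:
            raise IntegrityError(f"participant {s.participant_id} missing from split")
        samples.append(replace(s, split=assignment[s.participant_id]))
    out = Manifest(samples=samples, metadata=dict(manifest.metadata))
    _check_disjoint(out)
    return out


def _check_disjoint(manifest: Manifest) -> None:
    by_participant: dict[str, set[str]] = {}
    for s in manifest.samples:
        by_participant.setdefault(s.participant_id, set()).add(s.split)
    leaked = [p for p, splits in by_participant.items() if len(splits) > 1]
    if leaked:
        raise IntegrityError(f"participants in both splits: {leaked}")


_COLUMNS = ["sample_id", "participant_id", "fine_label", "coarse_label", "blanket", "split", "path"]


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    """Write the manifest as CSV (one row per sample, schema fixed)."""
    manifest.to_frame().to_csv(path, index=False)


def read_manifest(path: str | Path) -> Manifest:
    """Read a manifest CSV, validating labels and uniqueness.

    Malformed rows raise :class:`ManifestFormatError` carrying the
    1-based data row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ManifestFormatError(f"manifest missing columns: {missing}")
    samples = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            fine = FinePosture[row.fine_label]
        except KeyError:
            raise ManifestFormatError(
                f"unknown fine_label {row.fine_label!r}", row=i
            ) from None
        if row.blanket not in BLANKET_ORDER and not row.blanket.startswith("fused("):
            raise ManifestFormatError(f"unknown blanket {row.blanket!r}", row=i)
        if row.coarse_label != coarse_from_fine(fine).name:
            raise ManifestFormatError(
                f"coarse_label {row.coarse_label!r} inconsistent with "
                f"fine_label {row.fine_label!r}",
                row=i,
            )
        try:
            samples.append(
                Sample(
                    sample_id=row.sample_id,
                    participant_id=row.participant_id,
                    fine_label=fine,
                    blanket=row.blanket,
                    split=row.split,
                    path=row.path,
                )
            )
        except ManifestFormatError as exc:
            raise ManifestFormatError(str(exc), row=i) from None
    return Manifest(samples=samples)
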