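"""Randomized training-dataset construction.

To keep the model from overfitting any one anatomical region, training
slices from all patients are interleaved by sampling without replacement:
repeatedly pick a uniformly random patient among those with slices left,
then a uniformly random remaining slice of that patient.  The resulting
list is split into five contiguous sets (4 x ceil(N/5) + remainder for the
clinical N = 21,304, giving 4261/4261/4261/4261/4260), each materialized as
an aligned (CT input, skeleton-mask output) stack.  Ten distinct random
permutations of the five sets define the training orders whose influence
the experiment grid measures.  The test split is a single stack ordered
patient-by-patient, slice-by-slice, without randomization.
"""

from __future__ import annotations

import enum
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import DatasetError
from .preprocess import DEFAULT_LOWER_HU, DEFAULT_UPPER_HU, NormalizationMode, normalize
from .volume_io import CTVolume, MaskVolume, save_volume

__all__ = [
    "SliceRef",
    "SliceDataset",
    "TrainingOrder",
    "SplitRole",
    "shuffle_slices",
    "partition_sets",
    "assemble_set_volumes",
    "make_training_orders",
    "split_cohort",
    "build_training_dataset",
    "build_test_dataset",
    "save_dataset",
]

logger = logging.getLogger(__name__)

DEFAULT_N_SETS = 5
DEFAULT_N_ORDERS = 10
DEFAULT_TRAIN_FRACTION = 0.85


class SliceRef(NamedTuple):
    """One (patient, axial slice) sample, indices post-clipping and 0-based."""

    patient_id: str
    slice_index: int


class SplitRole(str, enum.Enum):
    TRAIN = "train"
    TEST = "test"


@dataclass(frozen=True)
class TrainingOrder:
    """A permutation of the set indices 1..n_sets; each set appears once."""

    order: tuple[int, ...]
    order_id: int

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(1, len(self.order) + 1)):
            raise ValueError(f"order {self.order!r} is not a permutation of 1..n")

    def zero_based(self) -> tuple[int, ...]:
        return tuple(i - 1 for i in self.order)


@dataclass
class SliceDataset:
    """A randomized slice list partitioned into aligned input/output stacks."""

    ordered_refs: list[SliceRef]
    sets: list[tuple[np.ndarray, np.ndarray]]  # (input stack, output stack)
    set_sizes: list[int]
    split_role: SplitRole
    seed: int | None = None

    def __post_init__(self) -> None:
        if [s[0].shape[0] for s in self.sets] != list(self.set_sizes):
            raise DatasetError("set stacks do not match set_sizes")
        for inp, out in self.sets:
            if inp.shape != out.shape:
                raise DatasetError("input and output stacks are not index-aligned")


def _check_pair(ct: CTVolume, mask: MaskVolume) -> None:
    if ct.shape != mask.shape:
        raise DatasetError(
            f"CT/mask shape mismatch for patient {ct.patient_id!r}: "
            f"{ct.shape} vs {mask.shape}"
        )


def shuffle_slices(
    patients: list[tuple[CTVolume, MaskVolume]], seed: int
) -> list[SliceRef]:
    """Randomize all (patient, slice) pairs by the two-stage uniform draw.

    Until no slices remain: pick a patient uniformly at random among those
    with remaining slices, then one of that patient's remaining slices
    uniformly at random.  Deterministic given ``seed``.
    """
    for ct, mask in patients:
        _check_pair(ct, mask)
    rng = np.random.default_rng(seed)
    remaining = {ct.patient_id: list(range(ct.slice_count)) for ct, _ in patients}
    ids = [ct.patient_id for ct, _ in patients]
    if len(set(ids)) != len(ids):
        raise DatasetError("duplicate patient ids in cohort")
    refs: list[SliceRef] = []
    alive = list(ids)
    while alive:
        pid = alive[int(rng.integers(len(alive)))]
        slices = remaining[pid]
        j = int(rng.integers(len(slices)))
        refs.append(SliceRef(pid, slices.pop(j)))
        if not slices:
            alive.remove(pid)
    return refs


def partition_sets(
    refs: list[SliceRef], n_sets: int = DEFAULT_N_SETS
) -> tuple[list[int], list[list[SliceRef]]]:
    """Split the shuffled list into contiguous sets.

    The first ``n_sets - 1`` sets get ceil(N/n) slices and the last the
    remainder; when that remainder would be non-positive the split falls
    back to balanced sizes (logged).
    """
    n = len(refs)
    if n_sets < 1:
        raise DatasetError("n_sets must be >= 1")
    if n < n_sets:
        raise DatasetError(f"{n} slices cannot fill {n_sets} sets")
    head = math.ceil(n / n_sets)
    last = n - (n_sets - 1) * head
    if last <= 0:
        sizes = [len(c) for c in np.array_split(np.arange(n), n_sets)]
        logger.warning(
            "ceil-rule split of %d into %d sets is infeasible; using balanced sizes %s",
            n, n_sets, sizes,
        )
    else:
        sizes = [head] * (n_sets - 1) + [last]
    chunks, start = [], 0
    for s in sizes:
        chunks.append(refs[start : start + s])
        start += s
    return sizes, chunks


def assemble_set_volumes(
    chunk: list[SliceRef],
    patients: dict[str, tuple[CTVolume, MaskVolume]],
    mode: NormalizationMode | str = NormalizationMode.A_INTERPATIENT_INTRASET,
    norm_anchors: tuple[float, float] = (DEFAULT_LOWER_HU, DEFAULT_UPPER_HU),
) -> tuple[np.ndarray, np.ndarray]:
    """Materialize one set as aligned (input, output) stacks.

    Under Experiment A the 0-255 normalization is applied here, over the
    whole multi-patient stack (the anchors are the thresholding bounds);
    under Experiment B inputs arrive already normalized per patient.
    """
    mode = NormalizationMode(mode)
    inputs, outputs = [], []
    for ref in chunk:
        try:
            ct, mask = patients[ref.patient_id]
        except KeyError:
            raise DatasetError(f"unresolvable patient id {ref.patient_id!r}") from None
        if not 0 <= ref.slice_index < ct.slice_count:
            raise DatasetError(f"unresolvable slice {ref!r}")
        inputs.append(ct.voxels[ref.slice_index])
        outputs.append(mask.voxels[ref.slice_index])
    input_stack = np.stack(inputs)
    output_stack = np.stack(outputs).astype(np.uint8)
    if mode is NormalizationMode.A_INTERPATIENT_INTRASET:
        input_stack = normalize(input_stack, *norm_anchors)
    return input_stack, output_stack


def make_training_orders(
    n_orders: int = DEFAULT_N_ORDERS, n_sets: int = DEFAULT_N_SETS, seed: int = 0
) -> list[TrainingOrder]:
    """Draw pairwise-distinct random permutations of the set indices."""
    if n_orders < 1:
        raise DatasetError("n_orders must be >= 1")
    if n_orders > math.factorial(n_sets):
        raise DatasetError(
            f"cannot draw {n_orders} distinct orders from {n_sets}! = "
            f"{math.factorial(n_sets)} permutations"
        )
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    orders: list[TrainingOrder] = []
    while len(orders) < n_orders:
        perm = tuple(int(i) + 1 for i in rng.permutation(n_sets))
        if perm in seen:
            continue
        seen.add(perm)
        orders.append(TrainingOrder(order=perm, order_id=len(orders) + 1))
    return orders


def split_cohort(
    patients: list, train_fraction: float = DEFAULT_TRAIN_FRACTION, seed: int = 0
) -> tuple[list, list]:
    """Patient-wise train/test split: floor(fraction*N) whole patients train."""
    if not 0 < train_fraction < 1:
        raise DatasetError("train_fraction must be in (0, 1)")
    n = len(patients)
    n_train = math.floor(train_fraction * n)
    if n_train == 0 or n_train == n:
        raise DatasetError(
            f"split of {n} patients at fraction {train_fraction} leaves an empty group"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [patients[i] for i in sorted(perm[:n_train])]
    test = [patients[i] for i in sorted(perm[n_train:])]
    return train, test


def build_training_dataset(
    patients: list[tuple[CTVolume, MaskVolume]],
    seed: int,
    mode: NormalizationMode | str = NormalizationMode.A_INTERPATIENT_INTRASET,
    n_sets: int = DEFAULT_N_SETS,
    norm_anchors: tuple[float, float] = (DEFAULT_LOWER_HU, DEFAULT_UPPER_HU),
) -> SliceDataset:
    """Shuffle, partition and materialize the training dataset."""
    refs = shuffle_slices(patients, seed)
    sizes, chunks = partition_sets(refs, n_sets)
    lookup = {ct.patient_id: (ct, mask) for ct, mask in patients}
    sets = [assemble_set_volumes(c, lookup, mode, norm_anchors) for c in chunks]
    return SliceDataset(
        ordered_refs=refs, sets=sets, set_sizes=sizes,
        split_role=SplitRole.TRAIN, seed=seed,
    )


def build_test_dataset(
    patients: list[tuple[CTVolume, MaskVolume]],
    mode: NormalizationMode | str = NormalizationMode.A_INTERPATIENT_INTRASET,
    norm_anchors: tuple[float, float] = (DEFAULT_LOWER_HU, DEFAULT_UPPER_HU),
) -> SliceDataset:
    """Single unshuffled set: patient-by-patient, slice-by-slice."""
    refs = [
        SliceRef(ct.patient_id, s)
        for ct, _ in patients
        for s in range(ct.slice_count)
    ]
    if not refs:
        raise DatasetError("empty test cohort")
    lookup = {ct.patient_id: (ct, mask) for ct, mask in patients}
    for ct, mask in patients:
        _check_pair(ct, mask)
    stack = assemble_set_volumes(refs, lookup, mode, norm_anchors)
    return SliceDataset(
        ordered_refs=refs, sets=[stack], set_sizes=[len(refs)],
        split_role=SplitRole.TEST, seed=None,
    )


def save_dataset(dataset: SliceDataset, out_dir: str | os.PathLike) -> None:
    """Persist each set as two NIfTI stacks plus a sidecar JSON of SliceRefs."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    start = 0
    for k, ((inp, out), size) in enumerate(zip(dataset.sets, dataset.set_sizes), start=1):
        save_volume(CTVolume(inp.astype(np.float64), patient_id=f"set{k}"),
                    os.path.join(out_dir, f"set{k}_input.nii.gz"))
        save_volume(MaskVolume(out, patient_id=f"set{k}"),
                    os.path.join(out_dir, f"set{k}_output.nii.gz"))
        refs = dataset.ordered_refs[start : start + size]
        start += size
        with open(os.path.join(out_dir, f"set{k}_refs.json"), "w") as fh:
            json.dump(
                {
                    "split_role": dataset.split_role.value,
                    "seed": dataset.seed,
                    "set_index": k,
                    "refs": [{"patient_id": r.patient_id, "slice_index": r.slice_index}
                             for r in refs],
                },
                fh,
                indent=1,
            )
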