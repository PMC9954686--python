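"""Subject-level stratified splitting, experiment label schemes and the
healthy-control noise-insertion challenge.

The stratified 80/10/10 split uses a floor/floor/remainder convention per
class: train = floor(0.8 n), val = floor(0.1 n), test = the remainder.
This is the unique simple rounding rule consistent with both published
split-size triples (226/27/31 from class sizes 54/99/131, and
1167/144/149 from 577/108/775).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SplitSpec",
    "ExperimentScheme",
    "SCHEMES",
    "stratified_split",
    "split_sizes",
    "apply_scheme",
    "insert_hc_noise",
]

SPLITS = ("train", "val", "test")

EXCLUDE = "EXCLUDE"

#: experiment label maps, named as in the published model identifiers
SCHEMES = {
    "AD_HC_MCI": {"AD": "AD", "HC": "HC", "MCI": "MCI"},
    "ADMCI_HC": {"AD": "ADMCI", "HC": "HC", "MCI": "ADMCI"},
    "AD_HCMCI": {"AD": "AD", "HC": "HCMCI", "MCI": "HCMCI"},
    "AD_HC": {"AD": "AD", "HC": "HC", "MCI": EXCLUDE},
    "HC_MCI": {"AD": EXCLUDE, "HC": "HC", "MCI": "MCI"},
}


@dataclass(frozen=True)
class ExperimentScheme:
    name: str
    label_map: dict[str, str]

    def __post_init__(self):
        out_labels = {v for v in self.label_map.values() if v != EXCLUDE}
        if len(out_labels) < 2:
            raise ValueError("a scheme needs at least two output labels")


def get_scheme(name: str) -> ExperimentScheme:
    if name not in SCHEMES:
        raise ValueError(f"unknown scheme {name!r}; choose from {sorted(SCHEMES)}")
    return ExperimentScheme(name=name, label_map=dict(SCHEMES[name]))


@dataclass(frozen=True)
class SplitSpec:
    """Subject-level split assignment (all slices of a subject share it)."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int
    class_counts: dict[str, int]

    def subjects_in(self, split: str) -> list[str]:
        return [s for s, sp in self.assignment.items() if sp == split]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"subject_id": s, "split": sp} for s, sp in self.assignment.items()]
        )


def split_sizes(n: int, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
                ) -> tuple[int, int, int]:
    """floor/floor/remainder split sizes for one class of ``n`` subjects."""
    n_train = math.floor(fractions[0] * n)
    n_val = math.floor(fractions[1] * n)
    return n_train, n_val, n - n_train - n_val


def stratified_split(subjects_by_class: dict[str, list[str]] | dict[str, int],
                     fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     seed: int = 0) -> SplitSpec:
    """Seeded stratified subject split.

    ``subjects_by_class`` maps each class label either to its subject-id
    list or to a bare count (ids are then synthesized), so the split
    arithmetic can be checked directly against published sizes.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    class_counts: dict[str, int] = {}
    for label in sorted(subjects_by_class):
        members = subjects_by_class[label]
        if isinstance(members, int):
            members = [f"{label}{i:04d}" for i in range(members)]
        members = list(members)
        class_counts[label] = len(members)
        order = rng.permutation(len(members))
        n_train, n_val, _ = split_sizes(len(members), fractions)
        for rank, idx in enumerate(order):
            if rank < n_train:
                split = "train"
            elif rank < n_train + n_val:
                split = "val"
            else:
                split = "test"
            assignment[members[idx]] = split
    return SplitSpec(assignment=assignment, fractions=tuple(fractions),
                     seed=seed, class_counts=class_counts)


def apply_scheme(manifest: pd.DataFrame, scheme: ExperimentScheme | str) -> pd.DataFrame:
    """Remap manifest labels for one experiment; split assignment untouched.

    Rows whose label maps to EXCLUDE are dropped so the identical subject
    split can be reused across experiments.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    unknown = set(manifest["label"]) - set(scheme.label_map)
    if unknown:
        raise ValueError(f"manifest labels {sorted(unknown)} not covered by scheme")
    out = manifest.copy()
    out["label"] = out["label"].map(scheme.label_map)
    return out[out["label"] != EXCLUDE].reset_index(drop=True)


def insert_hc_noise(manifest: pd.DataFrame, n_to_ad: int, n_to_mci: int,
                    seed: int = 0) -> pd.DataFrame:
    """Noise challenge: relabel healthy-control subjects as dementia in the
    *training* ground truth only; evaluation rows keep their true labels.

    Returns a manifest copy with an added ``train_label`` column holding
    the (possibly corrupted) labels used for training.
    """
    if n_to_ad < 0 or n_to_mci < 0:
        raise ValueError("insertion counts must be nonnegative")
    hc_subjects = sorted(manifest.loc[manifest["label"] == "HC", "subject_id"].unique())
    if n_to_ad + n_to_mci > len(hc_subjects):
        raise ValueError(
            f"requested {n_to_ad + n_to_mci} HC subjects but only {len(hc_subjects)} available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(hc_subjects)[: n_to_ad + n_to_mci]
    to_ad = set(chosen[:n_to_ad])
    to_mci = set(chosen[n_to_ad:])
    out = manifest.copy()
    out["train_label"] = out["label"]
    out.loc[out["subject_id"].isin(to_ad), "train_label"] = "AD"
    out.loc[out["subject_id"].isin(to_mci), "train_label"] = "MCI"
    return out
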