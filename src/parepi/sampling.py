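"""Positive/negative sample construction and stratified splits.

A cognate complex yields one positive sample: its paratope and epitope images
rendered in their native mutual orientation.  Negative samples come from three
generators — pairing the paratope of one complex with the epitope of another
(non-cognate), re-rendering the epitope with an extra in-plane rotation, or
with an in-plane translation.  Rotation angles are multiples of 30 degrees
with magnitude >= 60 (smaller rotations are treated as near-native by the
screening binder rule, so they would make ambiguous negatives); translations
must displace by at least 8 A, more than a typical residue-circle radius, so
the shifted pose is unambiguously wrong.

The train/test split is done at the complex level (80/20), with ten stratified
subtrain/validation folds (90/10) inside the training set; negative samples
are only ever built from complexes on one side of the split.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .config import Config
from .imaging import PatchImage, imagify_complex
from .structio import ComplexRecord

MIN_ROTATION_DEG = 60.0
MIN_TRANSLATION_A = 8.0


@dataclasses.dataclass
class SamplePair:
    paratope_image: PatchImage
    epitope_image: PatchImage
    label: int
    provenance: str               # "cognate" | "noncognate(p,e)" | "rotated(a)" | ...
    complex_id: str               # source of the paratope image
    partner_id: str               # source of the epitope image

    def tensor(self) -> np.ndarray:
        """H x W x 6 array: paratope RGB in channels 0-2, epitope RGB in 3-5."""
        p, e = self.paratope_image.pixels, self.epitope_image.pixels
        if p.shape != e.shape:
            raise ValueError("paratope and epitope images must share size")
        return np.concatenate([p, e], axis=-1)


def make_positive(record: ComplexRecord, config: Config) -> SamplePair:
    """Cognate pair, label 1."""
    para, epi = imagify_complex(record, config.imaging, config.interface)
    return SamplePair(para, epi, 1, "cognate", record.id, record.id)


def make_noncognate(record_a: ComplexRecord, record_b: ComplexRecord,
                    config: Config) -> SamplePair:
    """Paratope of complex A against the epitope of complex B, label 0."""
    if record_a.id == record_b.id:
        raise ValueError("non-cognate pairing requires two distinct complexes")
    para, _ = imagify_complex(record_a, config.imaging, config.interface)
    _, epi = imagify_complex(record_b, config.imaging, config.interface)
    return SamplePair(para, epi, 0,
                      f"noncognate({record_a.id},{record_b.id})",
                      record_a.id, record_b.id)


def make_rotated(record: ComplexRecord, angle_deg: float, config: Config) -> SamplePair:
    """Cognate pair with the epitope image rotated in-plane, label 0."""
    a = float(angle_deg) % 360.0
    signed = a - 360.0 if a > 180.0 else a
    if a % 30.0 != 0.0 or abs(signed) < MIN_ROTATION_DEG:
        raise ValueError(
            f"rotation angle must be a multiple of 30 with |angle| >= "
            f"{MIN_ROTATION_DEG:g}, got {angle_deg}")
    para, epi = imagify_complex(record, config.imaging, config.interface,
                                epitope_rotation_deg=angle_deg)
    return SamplePair(para, epi, 0, f"rotated({angle_deg:g})",
                      record.id, record.id)


def make_translated(record: ComplexRecord, du_A: float, dv_A: float,
                    config: Config) -> SamplePair:
    """Cognate pair with the epitope image shifted in-plane, label 0."""
    if float(np.hypot(du_A, dv_A)) < MIN_TRANSLATION_A:
        raise ValueError(
            f"translation magnitude must be >= {MIN_TRANSLATION_A:g} A")
    para, epi = imagify_complex(record, config.imaging, config.interface,
                                epitope_translation_A=(du_A, dv_A))
    return SamplePair(para, epi, 0, f"translated({du_A:g},{dv_A:g})",
                      record.id, record.id)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SplitPlan:
    train: list[str]
    test: list[str]
    folds: list[tuple[list[str], list[str]]]   # (subtrain ids, validation ids)
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed, "train": self.train, "test": self.test,
            "folds": [{"subtrain": s, "validation": v} for s, v in self.folds],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        folds = [(f["subtrain"], f["validation"]) for f in d["folds"]]
        return cls(d["train"], d["test"], folds, d["seed"])


def build_splits(complex_ids: list[str], seed: int,
                 test_fraction: float = 0.2, n_folds: int = 10) -> SplitPlan:
    """Complex-level 80/20 split plus ten 90/10 subtrain/validation folds.

    Deterministic for a given seed.  Because every complex contributes the
    same bundle of samples (one positive plus the configured negatives), a
    complex-balanced fold partition is stratified at the sample level.
    """
    ids = sorted(complex_ids)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} complexes, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(len(ids)))
    shuffled = [ids[i] for i in perm]
    n_test = int(round(test_fraction * len(ids)))
    test = sorted(shuffled[:n_test])
    train = [i for i in shuffled if i not in set(test)]
    if len(train) < n_folds:
        raise ValueError("too few training complexes for the fold count")
    folds = []
    groups: list[list[str]] = [[] for _ in range(n_folds)]
    for k, cid in enumerate(train):
        groups[k % n_folds].append(cid)
    for k in range(n_folds):
        val = sorted(groups[k])
        sub = sorted(set(train) - set(val))
        folds.append((sub, val))
    return SplitPlan(train=sorted(train), test=test, folds=folds, seed=seed)


def write_sample_manifest(samples, plan: SplitPlan, path: str) -> None:
    """TSV manifest of samples with their split side and validation fold."""
    import pandas as pd
    val_fold = {}
    for k, (_, val) in enumerate(plan.folds):
        for cid in val:
            val_fold[cid] = k
    rows = []
    test = set(plan.test)
    for i, s in enumerate(samples):
        side = "test" if s.complex_id in test else "train"
        rows.append({
            "sample_id": i, "complex_id": s.complex_id, "partner_id": s.partner_id,
            "label": s.label, "provenance": s.provenance, "split": side,
            "val_fold": val_fold.get(s.complex_id, -1) if side == "train" else -1,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
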