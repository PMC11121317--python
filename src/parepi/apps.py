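"""End-to-end drivers: docking-pose rescoring and paratope-library screening.

Rescoring images every docking pose of a complex, scores it with the model
ensemble, and reports the rank of the near-native pose among all poses (rank 1
is the highest score; ties break deterministically by pose id).

Screening renders a target epitope at the 12 in-plane rotations that are
multiples of 30 degrees and scores every (paratope, rotated epitope)
combination.  A paratope counts as a binder when it scores at or above the
threshold at rotations 0, +30 and -30 degrees simultaneously; the library is
ranked by the maximum score over the 12 rotations.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .cnn import ModelEnsemble
from .config import Config
from .imaging import (FrameError, PatchImage, build_frame, epitope_frame,
                      imagify_complex, render_patch)
from .structio import ComplexRecord, NoInterfaceError, find_interface

logger = logging.getLogger(__name__)

SCREEN_ANGLES = tuple(float(a) for a in range(0, 360, 30))


@dataclasses.dataclass
class PoseScore:
    complex_id: str
    pose_id: str
    near_native: bool
    score: float
    rank: int


@dataclasses.dataclass
class ScreenResult:
    paratope_id: str
    angle_scores: dict[float, float]
    binder: bool
    rank_metric: float


def _pair_tensor(para: PatchImage, epi: PatchImage) -> np.ndarray:
    return np.concatenate([para.pixels, epi.pixels], axis=-1)


def rescore_poses(poses: list[tuple[str, ComplexRecord, bool]],
                  ensemble: ModelEnsemble, config: Config,
                  complex_id: str = "complex") -> list[PoseScore]:
    """Score and rank docking poses of one complex.

    ``poses`` holds (pose_id, parsed pose record, near_native flag) triples;
    exactly one pose must be flagged near-native.  Poses without any interface
    under the contact cutoff get score 0 and sort last.
    """
    if sum(1 for _, _, nn in poses if nn) != 1:
        raise ValueError("exactly one pose must be flagged near-native")
    tensors, scored = [], []
    for pose_id, record, nn in poses:
        try:
            pimg, eimg = imagify_complex(record, config.imaging, config.interface)
            tensors.append((pose_id, nn, _pair_tensor(pimg, eimg)))
        except (NoInterfaceError, FrameError):
            logger.warning("pose %s has no usable interface; assigned score 0",
                           pose_id)
            scored.append((pose_id, nn, 0.0))
    if tensors:
        X = np.stack([t for _, _, t in tensors])
        sc = ensemble.score(X)
        scored.extend((pid, nn, float(s)) for (pid, nn, _), s in zip(tensors, sc))
    scored.sort(key=lambda t: (-t[2], t[0]))
    return [PoseScore(complex_id, pid, nn, s, rank)
            for rank, (pid, nn, s) in enumerate(scored, start=1)]


def near_native_rank(pose_scores: list[PoseScore]) -> int:
    return next(p.rank for p in pose_scores if p.near_native)


def average_near_native_rank(per_complex: list[list[PoseScore]]) -> float:
    """Mean rank of the near-native pose across complexes."""
    return float(np.mean([near_native_rank(ps) for ps in per_complex]))


def screen_library(epitope_record: ComplexRecord,
                   library: list[tuple[str, PatchImage]],
                   ensemble: ModelEnsemble, config: Config,
                   tau: float = 0.5, rank_metric: str = "max") -> list[ScreenResult]:
    """Screen a paratope library against one epitope at 12 rotations.

    Returns results sorted best-first by the rank metric (max over rotation
    scores by default, mean via ``rank_metric="mean"``), ties broken by
    paratope id.
    """
    if not library:
        raise ValueError("paratope library is empty")
    paratope_own, epitope = find_interface(epitope_record, config.interface.cutoff,
                                           config.interface.cdr_radius)
    fe = epitope_frame(build_frame(paratope_own, config.imaging.mode),
                       epitope, config.imaging.mode)
    rotated = {a: render_patch(epitope, config.imaging, mirror=True,
                               rotation_deg=a, frame=fe)
               for a in SCREEN_ANGLES}
    results = []
    for pid, pimg in library:
        try:
            X = np.stack([_pair_tensor(pimg, rotated[a]) for a in SCREEN_ANGLES])
        except ValueError as exc:
            logger.warning("skipping library entry %s: %s", pid, exc)
            continue
        sc = ensemble.score(X)
        angle_scores = {a: float(s) for a, s in zip(SCREEN_ANGLES, sc)}
        binder = (angle_scores[0.0] >= tau and angle_scores[30.0] >= tau
                  and angle_scores[330.0] >= tau)
        metric = max(angle_scores.values()) if rank_metric == "max" \
            else float(np.mean(list(angle_scores.values())))
        results.append(ScreenResult(pid, angle_scores, binder, metric))
    results.sort(key=lambda r: (-r.rank_metric, r.paratope_id))
    return results


def pose_scores_to_frame(pose_scores: list[PoseScore]):
    import pandas as pd
    return pd.DataFrame([dataclasses.asdict(p) for p in pose_scores])


def screen_results_to_frame(results: list[ScreenResult]):
    import pandas as pd
    rows = []
    for rank, r in enumerate(results, start=1):
        row = {"rank": rank, "paratope_id": r.paratope_id,
               "binder": r.binder, "rank_metric": r.rank_metric}
        row.update({f"score_{int(a)}": s for a, s in r.angle_scores.items()})
        rows.append(row)
    return pd.DataFrame(rows)
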