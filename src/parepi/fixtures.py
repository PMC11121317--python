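"""Synthetic toy complexes and labelled image-pair tasks.

A toy complex is two roughly planar residue clouds facing each other 4-6 A
apart: a "paratope" cloud split over heavy and light chains and an "epitope"
cloud on an antigen chain.  In ``matched`` mode the epitope points sit
opposite the paratope points (small lateral jitter) and each epitope residue
is the fixed chemical complement of its paratope partner (Arg/Lys opposite
Asp/Glu, aromatics opposite polar partners), so cognate pairs are both
shape- and colour-complementary — the signal the classifier is meant to
learn.  ``mismatched`` mode draws independent layouts and compositions.

Residues carry minimal atom sets (a C-alpha plus 0-3 pseudo side-chain atoms
whose mean is the intended C-mu), coordinates are quantised to the PDB's
3-decimal precision, and every generated complex is serialised to PDB text
and re-read through the public parser, so fixtures exercise exactly the same
code path as real data.  Geometric realism (CDR loops, packing, energetics)
is not attempted.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import Config
from .sampling import (SamplePair, SplitPlan, build_splits, make_noncognate,
                       make_positive, make_rotated, make_translated)
from .structio import ComplexRecord, parse_complex

#: paratope-side palette (paratope-like bias toward aromatic/charged residues)
PARATOPE_PALETTE = "RKYWFSGH"
#: fixed chemical complement used in matched mode
COMPLEMENT = {"R": "D", "K": "E", "Y": "N", "W": "Q",
              "F": "L", "S": "T", "G": "A", "H": "V"}
AA_3LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

ROTATION_ANGLES = (60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 240.0, 270.0, 300.0)


@dataclasses.dataclass
class ToyComplexSpec:
    n_paratope: int = 10
    n_epitope: int = 10
    separation: float = 5.0      # Angstrom between the two patch planes
    mode: str = "matched"        # "matched" | "mismatched"
    seed: int = 0
    n_scaffold: int = 0          # extra non-interface antigen residues
    lateral_jitter: float = 0.4  # matched-mode epitope jitter, Angstrom
    depth_jitter: float = 0.6    # out-of-plane scatter, Angstrom
    max_pair_gap: float = 5.8    # matched pairs stay inside the contact cutoff
    r_min: float = 1.5           # in-plane placement annulus, Angstrom
    r_max: float = 9.0
    min_spacing: float = 2.8     # minimum in-plane distance between residues


def _place_points(rng, n, r_min, r_max, min_spacing) -> np.ndarray:
    pts: list[np.ndarray] = []
    while len(pts) < n:
        r = np.sqrt(rng.uniform(r_min ** 2, r_max ** 2))
        th = rng.uniform(0, 2 * np.pi)
        p = np.array([r * np.cos(th), r * np.sin(th)])
        if all(np.linalg.norm(p - q) >= min_spacing for q in pts):
            pts.append(p)
    return np.array(pts)


def _atom_line(serial, name, resname, chain, resseq, xyz, element) -> str:
    x, y, z = xyz
    return (f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}")


def _residue_atoms(rng, aa: str, c_mu: np.ndarray):
    """C-alpha plus pseudo side-chain atoms whose mean equals c_mu."""
    ca = c_mu + np.array([0.5, 0.5, -0.8])
    if aa == "G":
        return [("CA", c_mu)]          # glycine: C-mu coincides with C-alpha
    atoms = [("CA", ca)]
    n_sc = int(rng.integers(1, 4))
    d1 = np.array([0.4, 0.0, 0.2])
    d2 = np.array([0.0, 0.4, -0.1])
    if n_sc == 1:
        atoms.append(("CB", c_mu))
    elif n_sc == 2:
        atoms += [("CB", c_mu + d1), ("CG", c_mu - d1)]
    else:
        atoms += [("CB", c_mu + d1), ("CG", c_mu + d2), ("CD", c_mu - d1 - d2)]
    return atoms


def generate_toy_complex(spec: ToyComplexSpec,
                         complex_id: str = "toy") -> tuple[ComplexRecord, str]:
    """Generate one toy complex; returns the parsed record and its PDB text.

    Deterministic per seed.  The record is obtained by serialising to PDB and
    re-parsing with :func:`parepi.structio.parse_complex`, so fixture data
    flows through the identical public pipeline as real structures.
    """
    if spec.n_paratope < 3 or spec.n_epitope < 3:
        raise ValueError("need at least 3 residues per patch")
    rng = np.random.default_rng(spec.seed)
    para_xy = _place_points(rng, spec.n_paratope, spec.r_min, spec.r_max,
                            spec.min_spacing)
    para_z = rng.normal(0.0, spec.depth_jitter, spec.n_paratope)
    para_aa = [PARATOPE_PALETTE[i] for i in
               rng.integers(0, len(PARATOPE_PALETTE), spec.n_paratope)]

    if spec.mode == "matched":
        n_match = min(spec.n_paratope, spec.n_epitope)
        epi_xy = para_xy[:n_match] + rng.normal(0, spec.lateral_jitter, (n_match, 2))
        # per-pair z gap clipped below the contact cutoff so every matched
        # pair is an interface contact by construction
        gaps = np.clip(spec.separation
                       + rng.normal(0.0, spec.depth_jitter, n_match),
                       0.5, spec.max_pair_gap)
        epi_z = para_z[:n_match] + gaps
        if spec.n_epitope > n_match:
            extra = _place_points(rng, spec.n_epitope - n_match,
                                  spec.r_min, spec.r_max, spec.min_spacing)
            epi_xy = np.vstack([epi_xy, extra])
            epi_z = np.concatenate([
                epi_z, spec.separation + rng.normal(0.0, spec.depth_jitter,
                                                    spec.n_epitope - n_match)])
        epi_aa = [COMPLEMENT[a] for a in para_aa[:n_match]]
        epi_aa += [COMPLEMENT[PARATOPE_PALETTE[i]] for i in
                   rng.integers(0, len(PARATOPE_PALETTE), spec.n_epitope - n_match)]
    elif spec.mode == "mismatched":
        epi_xy = _place_points(rng, spec.n_epitope, spec.r_min, spec.r_max,
                               spec.min_spacing)
        epi_aa = [COMPLEMENT[PARATOPE_PALETTE[i]] for i in
                  rng.integers(0, len(PARATOPE_PALETTE), spec.n_epitope)]
        epi_z = spec.separation + rng.normal(0.0, spec.depth_jitter, spec.n_epitope)
    else:
        raise ValueError(f"unknown complementarity mode {spec.mode!r}")

    lines = []
    serial = 1

    def emit(chain, resseq, aa, c_mu):
        nonlocal serial
        resname = AA_3LETTER[aa]
        for name, xyz in _residue_atoms(rng, aa, np.round(c_mu, 3)):
            lines.append(_atom_line(serial, name, resname, chain, resseq,
                                    np.round(xyz, 3), "C"))
            serial += 1

    n_heavy = max(1, min(spec.n_paratope - 1, int(round(spec.n_paratope * 0.6))))
    for i in range(spec.n_paratope):
        chain = "H" if i < n_heavy else "L"
        resseq = i + 1 if i < n_heavy else i - n_heavy + 1
        emit(chain, resseq, para_aa[i],
             np.array([para_xy[i, 0], para_xy[i, 1], para_z[i]]))
    for i in range(spec.n_epitope):
        emit("A", i + 1, epi_aa[i],
             np.array([epi_xy[i, 0], epi_xy[i, 1], epi_z[i]]))
    for i in range(spec.n_scaffold):
        c = np.array([rng.uniform(-10, 10), rng.uniform(-10, 10),
                      spec.separation + rng.uniform(12.0, 25.0)])
        emit("A", spec.n_epitope + 1 + i, "S", c)
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"
    record = parse_complex(pdb_text, {"H": "H", "L": "L", "A": "A"},
                           complex_id=complex_id)
    return record, pdb_text


# ---------------------------------------------------------------------------
# image-pair task
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ImageTask:
    samples: list[SamplePair]
    manifest: pd.DataFrame
    plan: SplitPlan
    records: dict[str, ComplexRecord]
    pdb_texts: dict[str, str] = dataclasses.field(default_factory=dict)

    def tensors(self, split: str | None = None):
        """(X, y) arrays, optionally restricted to the 'train' or 'test' side."""
        sel = self.manifest if split is None else \
            self.manifest[self.manifest["split"] == split]
        idx = sel["sample_id"].to_numpy()
        X = np.stack([self.samples[i].tensor() for i in idx]).astype(np.float32)
        y = sel["label"].to_numpy().astype(np.float64)
        return X, y

    def fold_indices(self, fold: int):
        """Positional (subtrain, validation) indices into the train tensors."""
        train = self.manifest[self.manifest["split"] == "train"].reset_index(drop=True)
        val_mask = (train["val_fold"] == fold).to_numpy()
        return np.flatnonzero(~val_mask), np.flatnonzero(val_mask)


def generate_image_task(n_complexes: int, seed: int, config: Config,
                        ratio: tuple[int, int, int] = (1, 1, 1),
                        n_folds: int = 10) -> ImageTask:
    """Generate a labelled paratope/epitope image-pair dataset.

    ``ratio`` gives the number of (non-cognate, rotated, translated) negatives
    per positive.  Complexes are split 80/20 before negatives are drawn, and
    non-cognate partners are only taken from the same side of the split.
    """
    if n_complexes < 20:
        raise ValueError("need at least 20 complexes for a meaningful task")
    rng = np.random.default_rng(seed)
    records: dict[str, ComplexRecord] = {}
    pdb_texts: dict[str, str] = {}
    for i in range(n_complexes):
        cid = f"toy{i:03d}"
        n_res = int(rng.integers(8, 15))
        spec = ToyComplexSpec(
            n_paratope=n_res,
            n_epitope=n_res,
            separation=float(rng.uniform(4.0, 5.5)),
            mode="matched",
            seed=int(rng.integers(0, 2 ** 31)),
        )
        records[cid], pdb_texts[cid] = generate_toy_complex(spec, complex_id=cid)

    plan = build_splits(sorted(records), seed=seed, n_folds=n_folds)
    side_of = {cid: "test" for cid in plan.test}
    side_of.update({cid: "train" for cid in plan.train})
    pool = {"train": plan.train, "test": plan.test}

    samples: list[SamplePair] = []
    for cid in sorted(records):
        rec = records[cid]
        side = side_of[cid]
        samples.append(make_positive(rec, config))
        n_non, n_rot, n_tr = ratio
        mates = [c for c in pool[side] if c != cid]
        for _ in range(n_non):
            partner = mates[int(rng.integers(0, len(mates)))]
            samples.append(make_noncognate(rec, records[partner], config))
        for _ in range(n_rot):
            angle = ROTATION_ANGLES[int(rng.integers(0, len(ROTATION_ANGLES)))]
            samples.append(make_rotated(rec, angle, config))
        for _ in range(n_tr):
            mag = float(rng.uniform(8.0, 14.0))
            th = float(rng.uniform(0, 2 * np.pi))
            samples.append(make_translated(rec, mag * np.cos(th),
                                           mag * np.sin(th), config))

    val_fold = {}
    for k, (_, val) in enumerate(plan.folds):
        for c in val:
            val_fold[c] = k
    rows = []
    for i, s in enumerate(samples):
        side = side_of[s.complex_id]
        rows.append({"sample_id": i, "complex_id": s.complex_id,
                     "partner_id": s.partner_id, "label": s.label,
                     "provenance": s.provenance, "split": side,
                     "val_fold": val_fold.get(s.complex_id, -1)
                     if side == "train" else -1})
    manifest = pd.DataFrame(rows)
    return ImageTask(samples, manifest, plan, records, pdb_texts)
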