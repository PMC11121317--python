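"""Reading antibody-antigen complexes and locating their binding interface.

Each residue is coarse-grained to a single C-mu pseudoatom, the arithmetic
mean of its heavy side-chain atom coordinates (the C-alpha for glycine and for
residues whose side chain is entirely unresolved).  A residue of the antibody
(antigen) belongs to the paratope (epitope) iff its C-mu lies within a cutoff
distance — 6 A by default — of the C-mu of any partner residue.  Members
farther than 40 A from the geometric centre of the CDRs are removed, which
prevents spurious secondary contacts on very large antigens from entering the
interface.

Curation applies, in order: the antigen must be a protein of >= 50 residues;
heavy and light chains must both be present (Fab/Fv); at most 50 residues may
have missing atomic coordinates; no UNK residues; and the interface must hold
at least three residues on each side.  Redundancy between complexes is removed
by greedy longest-antigen-first clustering on global sequence identity of the
concatenated CDRs (> 0.8) and the antigen (> 0.9).
"""

from __future__ import annotations

import dataclasses
import io
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from scipy.spatial.distance import cdist

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class StructureError(ValueError):
    """A declared chain is missing or the complex is structurally unusable."""


class PDBParseError(ValueError):
    """An ATOM/HETATM record could not be parsed (carries the line number)."""


class NoInterfaceError(ValueError):
    """No residue pair across the interface satisfies the contact cutoff."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    aa: str                                   # one-letter code; 'X' for UNK
    heavy_atoms: list[tuple[str, np.ndarray]]
    c_mu: np.ndarray

    @property
    def res_id(self) -> str:
        return f"{self.chain_id}{self.number}{self.icode}".strip()

    def side_chain_atoms(self) -> list[tuple[str, np.ndarray]]:
        return [(n, c) for n, c in self.heavy_atoms if n not in BACKBONE_ATOMS]


@dataclasses.dataclass
class ComplexRecord:
    id: str
    heavy_chain: list[Residue]
    light_chain: list[Residue]
    antigen_chains: dict[str, list[Residue]]
    cdr_annotation: set[tuple[str, str]] | None = None  # (chain_id, res_id)
    unk_residues: list[str] = dataclasses.field(default_factory=list)

    def antibody_residues(self) -> list[Residue]:
        return list(self.heavy_chain) + list(self.light_chain)

    def antigen_residues(self) -> list[Residue]:
        return [r for ch in self.antigen_chains.values() for r in ch]

    def antigen_sequence(self) -> str:
        return "".join(r.aa for r in self.antigen_residues())


@dataclasses.dataclass
class InterfacePatch:
    side: str                      # "paratope" | "epitope"
    members: list[Residue]
    partner_centroid: np.ndarray
    cdr_center: np.ndarray

    def c_mu_array(self) -> np.ndarray:
        return np.array([r.c_mu for r in self.members])


@dataclasses.dataclass
class CurationReport:
    kept: list[str]
    discarded: list[tuple[str, str]]

    def to_frame(self):
        import pandas as pd
        rows = [{"id": i, "status": "kept", "rule": ""} for i in self.kept]
        rows += [{"id": i, "status": "discarded", "rule": r} for i, r in self.discarded]
        return pd.DataFrame(rows, columns=["id", "status", "rule"])


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _validate_atom_lines(pdb_text: str) -> None:
    for ln, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except (ValueError, IndexError) as exc:
                raise PDBParseError(f"unparseable ATOM record at line {ln}") from exc


def _pick_altloc(atom):
    """Highest-occupancy conformer; ties broken toward altloc 'A'."""
    if not atom.is_disordered():
        return atom
    children = sorted(
        atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def _residue_from_biopdb(chain_id: str, res) -> Residue | None:
    resname = res.get_resname().strip()
    aa = protein_letters_3to1.get(resname, "X")
    seen: dict[str, list] = {}
    for atom in res.get_list():
        atom = _pick_altloc(atom)
        elem = (atom.element or "").strip().upper()
        if elem in ("H", "D"):
            continue
        name = atom.get_id().strip()
        seen[name] = atom.get_coord()
    heavy = [(n, np.asarray(c, dtype=float)) for n, c in seen.items()]
    if not heavy:
        return None
    side = [c for n, c in heavy if n not in BACKBONE_ATOMS]
    if side:
        c_mu = np.mean(np.asarray(side, dtype=float), axis=0)
    elif "CA" in seen:
        c_mu = np.asarray(seen["CA"], dtype=float)
    else:
        return None
    het, num, icode = res.get_id()
    return Residue(chain_id, num, icode.strip(), aa, heavy, c_mu)


def parse_complex(pdb_text: str, chain_spec: Mapping[str, str],
                  complex_id: str = "complex",
                  cdr_annotation: set[tuple[str, str]] | None = None) -> ComplexRecord:
    """Parse a single-complex PDB into a :class:`ComplexRecord`.

    ``chain_spec`` maps chain id to role: exactly one ``"H"``, one ``"L"``,
    and one or more ``"A"`` (antigen).  Altlocs keep the highest-occupancy
    conformer; UNK residues are retained with code ``'X'`` and listed in
    ``unk_residues``.
    """
    roles: dict[str, list[str]] = {"H": [], "L": [], "A": []}
    for cid, role in chain_spec.items():
        role = role.upper()
        if role not in roles:
            raise StructureError(f"unknown chain role {role!r} for chain {cid!r}")
        roles[role].append(cid)
    if len(roles["H"]) != 1 or len(roles["L"]) != 1 or not roles["A"]:
        raise StructureError(
            "chain_spec must assign exactly one heavy, one light and >=1 antigen chain")

    _validate_atom_lines(pdb_text)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(complex_id, io.StringIO(pdb_text))
    model = next(structure.get_models())
    present = {ch.get_id(): ch for ch in model.get_chains()}
    for cid in chain_spec:
        if cid not in present:
            raise StructureError(f"declared chain {cid!r} not found in PDB")

    unk: list[str] = []

    def extract(cid: str) -> list[Residue]:
        out = []
        for res in present[cid].get_list():
            het, num, icode = res.get_id()
            if het.strip() and res.get_resname().strip() != "UNK":
                continue  # waters / ligands
            r = _residue_from_biopdb(cid, res)
            if r is None:
                continue
            if r.aa == "X":
                unk.append(r.res_id)
            out.append(r)
        return out

    record = ComplexRecord(
        id=complex_id,
        heavy_chain=extract(roles["H"][0]),
        light_chain=extract(roles["L"][0]),
        antigen_chains={cid: extract(cid) for cid in roles["A"]},
        cdr_annotation=cdr_annotation,
        unk_residues=unk,
    )
    if not record.heavy_chain or not record.light_chain:
        raise StructureError("heavy and light chains must be non-empty (Fab/Fv)")
    if not record.antigen_residues():
        raise StructureError("antigen chains contain no residues")
    return record


# ---------------------------------------------------------------------------
# interface identification
# ---------------------------------------------------------------------------

def find_interface(record: ComplexRecord, cutoff_A: float = 6.0,
                   cdr_radius_A: float = 40.0) -> tuple[InterfacePatch, InterfacePatch]:
    """Identify the paratope and epitope patches of a complex.

    Membership uses the C-mu/C-mu distance cutoff; the 40 A filter is applied
    around the geometric centre of the CDR residues participating in the
    interface (or of all antibody interface residues when no CDR annotation is
    available).
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff must be positive")
    ab = record.antibody_residues()
    ag = record.antigen_residues()
    ab_mu = np.array([r.c_mu for r in ab])
    ag_mu = np.array([r.c_mu for r in ag])
    dist = cdist(ab_mu, ag_mu)
    ab_sel = (dist.min(axis=1) <= cutoff_A)
    ag_sel = (dist.min(axis=0) <= cutoff_A)
    para = [r for r, s in zip(ab, ab_sel) if s]
    epi = [r for r, s in zip(ag, ag_sel) if s]
    if not para or not epi:
        raise NoInterfaceError(
            f"{record.id}: no interface within {cutoff_A} A")

    if record.cdr_annotation:
        anchors = [r for r in para if (r.chain_id, r.res_id) in record.cdr_annotation]
        if not anchors:
            anchors = para
    else:
        anchors = para
    cdr_center = np.mean([r.c_mu for r in anchors], axis=0)

    para = [r for r in para if np.linalg.norm(r.c_mu - cdr_center) <= cdr_radius_A]
    epi = [r for r in epi if np.linalg.norm(r.c_mu - cdr_center) <= cdr_radius_A]
    if not para or not epi:
        raise NoInterfaceError(
            f"{record.id}: interface empty after {cdr_radius_A} A CDR-centre filter")

    para_centroid = np.mean([r.c_mu for r in para], axis=0)
    epi_centroid = np.mean([r.c_mu for r in epi], axis=0)
    paratope = InterfacePatch("paratope", para, epi_centroid, cdr_center)
    epitope = InterfacePatch("epitope", epi, para_centroid, cdr_center)
    return paratope, epitope


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CurationInput:
    """One complex plus the metadata the curation rules need."""

    record: ComplexRecord
    is_protein_antigen: bool = True
    n_missing_residues: int = 0


def curate(inputs: Sequence[CurationInput], cutoff_A: float = 6.0,
           cdr_radius_A: float = 40.0, min_interface: int = 3) -> CurationReport:
    """Apply the dataset-curation rules; each discard cites its first failing rule."""
    kept: list[str] = []
    discarded: list[tuple[str, str]] = []
    for item in inputs:
        rec = item.record
        if not item.is_protein_antigen or len(rec.antigen_residues()) < 50:
            discarded.append((rec.id, "antigen_size")); continue
        if not rec.heavy_chain or not rec.light_chain:
            discarded.append((rec.id, "fab_fv")); continue
        if item.n_missing_residues > 50:
            discarded.append((rec.id, "missing_residues")); continue
        if rec.unk_residues:
            discarded.append((rec.id, "unk_residues")); continue
        try:
            para, epi = find_interface(rec, cutoff_A, cdr_radius_A)
        except NoInterfaceError:
            discarded.append((rec.id, "interface_size")); continue
        if len(para.members) < min_interface or len(epi.members) < min_interface:
            discarded.append((rec.id, "interface_size")); continue
        kept.append(rec.id)
    return CurationReport(kept, discarded)


# ---------------------------------------------------------------------------
# redundancy removal
# ---------------------------------------------------------------------------

def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = 0.0
    a.extend_gap_score = 0.0
    return a


def sequence_identity(seq1: str, seq2: str,
                      aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matched positions / max(sequence lengths)."""
    if not seq1 or not seq2:
        return 0.0
    if aligner is None:
        aligner = _aligner()
    return float(aligner.score(seq1, seq2)) / max(len(seq1), len(seq2))


def deduplicate(complexes: Sequence[tuple[str, str, str]],
                cdr_identity: float = 0.8,
                ag_identity: float = 0.9) -> list[str]:
    """Greedy redundancy removal over (id, concatenated-CDR seq, antigen seq).

    Complexes are visited longest-antigen-first (ties by id); each unassigned
    complex opens a cluster and absorbs every later complex whose CDR identity
    exceeds ``cdr_identity`` AND antigen identity exceeds ``ag_identity``.
    Cluster representatives (longest antigen of their group) are kept, so the
    result is invariant under permutation of the input.
    """
    if not complexes:
        return []
    aligner = _aligner()
    order = sorted(complexes, key=lambda c: (-len(c[2]), c[0]))
    assigned = [False] * len(order)
    kept: list[str] = []
    for i, (cid, cdr_i, ag_i) in enumerate(order):
        if assigned[i]:
            continue
        assigned[i] = True
        kept.append(cid)
        for j in range(i + 1, len(order)):
            if assigned[j]:
                continue
            _, cdr_j, ag_j = order[j]
            if (sequence_identity(cdr_i, cdr_j, aligner) > cdr_identity
                    and sequence_identity(ag_i, ag_j, aligner) > ag_identity):
                assigned[j] = True
    return kept


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def read_chain_manifest(path: str):
    """TSV manifest: id, pdb_path, heavy_chain, light_chain, antigen_chains[, cdr_residues]."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "pdb_path", "heavy_chain", "light_chain", "antigen_chains"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chain manifest missing columns: {sorted(missing)}")
    return df


def load_complexes(manifest_df) -> list[ComplexRecord]:
    records = []
    for row in manifest_df.itertuples(index=False):
        spec = {row.heavy_chain: "H", row.light_chain: "L"}
        for cid in str(row.antigen_chains).split(","):
            spec[cid.strip()] = "A"
        cdr = None
        if getattr(row, "cdr_residues", ""):
            cdr = {tuple(tok.split(":", 1)) for tok in str(row.cdr_residues).split(",")}
        with open(row.pdb_path) as fh:
            records.append(parse_complex(fh.read(), spec, complex_id=row.id,
                                         cdr_annotation=cdr))
    return records


def write_curation_report(report: CurationReport, path: str) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False)
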