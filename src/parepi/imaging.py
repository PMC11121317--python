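"""Projection of interface patches to feature-coloured 2D images.

Each patch gets its own oriented frame from a principal component analysis of
its member coordinates: the top two principal axes span the image plane, the
third is the normal, sign-fixed to point toward the partner patch.  For a
standalone frame the in-plane e1 sign is fixed by requiring a non-negative
third central moment (skewness) of the projected u coordinates, and
e2 = n x e1 closes a right-handed orthonormal triple.  For a cognate pair the
epitope keeps its own plane but takes its in-plane axis from the paratope
frame (see :func:`epitope_frame`), so the two sides render as mutually
aligned views.  All conventions are intrinsic to the coordinates, which makes
the rendered images invariant under rigid motions of the complex.

Members are drawn as filled circles — one per residue C-mu (radius from the
residue-volume table) or one 1 A circle per heavy side-chain atom — coloured
by the P/I/H feature triple (or the four-colour scheme) and alpha-composited
over a white background.  Distance to the PCA plane maps linearly to
transparency, and circles are painted farthest-from-plane first so that
interface-proximal residues dominate overlaps.  Rasterisation is analytic
(hard-edged circle coverage at pixel centres), which keeps the output
bit-exactly deterministic.

The epitope image is mirrored about the u axis after projection: the two
patches are rendered as mutually facing views, which superimpose only after
one reflection, so mirroring makes spatially corresponding residues of a
cognate pair land at corresponding pixels.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .config import ImagingConfig, InterfaceConfig
from .structio import ComplexRecord, InterfacePatch, find_interface

logger = logging.getLogger(__name__)

FOUR_COLOR = {
    **{a: (0.0, 1.0, 0.0) for a in "FYWH"},   # aromatic -> green
    **{a: (1.0, 0.0, 0.0) for a in "RK"},     # positive -> red
    **{a: (0.0, 0.0, 1.0) for a in "DE"},     # negative -> blue
}
FALLBACK_COLOR = (0.5, 0.5, 0.5)  # unknown residue: neutral grey, logged


class FrameError(ValueError):
    """Patch coordinates are degenerate (collinear); no stable plane exists."""


@dataclasses.dataclass
class OrientedFrame:
    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    n: np.ndarray


@dataclasses.dataclass
class ProjectedPoint:
    u: float
    v: float
    depth: float
    aa: str
    radius: float


@dataclasses.dataclass
class PatchImage:
    pixels: np.ndarray          # H x W x 3, float in [0, 1]
    side: str
    mode: str
    scale: float
    angle: float = 0.0


# ---------------------------------------------------------------------------
# frames and projection
# ---------------------------------------------------------------------------

def _patch_coordinates(patch: InterfacePatch, mode: str) -> np.ndarray:
    if mode == "residue":
        return patch.c_mu_array()
    if mode == "atom":
        coords = [c for r in patch.members for _, c in r.side_chain_atoms()]
        if not coords:  # all-glycine edge: fall back to C-mu points
            return patch.c_mu_array()
        return np.asarray(coords, dtype=float)
    raise ValueError(f"unknown imaging mode {mode!r}")


def build_frame(patch: InterfacePatch, mode: str = "residue") -> OrientedFrame:
    """PCA frame of a patch, oriented toward the partner patch."""
    coords = _patch_coordinates(patch, mode)
    if coords.shape[0] < 3:
        raise FrameError("need at least 3 points for a PCA frame")
    origin = coords.mean(axis=0)
    centred = coords - origin
    cov = centred.T @ centred
    evals, evecs = np.linalg.eigh(cov)       # ascending eigenvalues
    if evals[1] <= 1e-9 * max(evals[2], 1.0):
        raise FrameError("patch coordinates are collinear or degenerate")
    e1 = evecs[:, 2]
    n = evecs[:, 0]
    if n @ (patch.partner_centroid - origin) < 0:
        n = -n
    u = centred @ e1
    skew = float(np.sum(u ** 3))
    if abs(skew) > 1e-9:
        if skew < 0:
            e1 = -e1
    else:
        # tie-break: orient so the maximum-u member has the lexicographically
        # smallest residue id among the two sign choices
        ids = [r.res_id for r in patch.members]
        if mode == "atom":
            ids = [r.res_id for r in patch.members for _ in r.side_chain_atoms()] or ids
        id_pos = ids[int(np.argmax(u))]
        id_neg = ids[int(np.argmax(-u))]
        if id_neg < id_pos:
            e1 = -e1
    e2 = np.cross(n, e1)
    return OrientedFrame(origin=origin, e1=e1, e2=e2, n=n)


def epitope_frame(paratope_frame: OrientedFrame, patch: InterfacePatch,
                  mode: str = "residue") -> OrientedFrame:
    """Frame for the epitope patch of a cognate pair.

    The plane is the epitope's own (top-two PCA axes; normal sign-fixed
    toward the paratope), but the in-plane orientation is transported from
    the paratope frame: e1 is the unit projection of the paratope's e1 onto
    the epitope plane.  A per-patch in-plane convention (such as the skewness
    rule used for standalone frames) is not reproducible across the two sides
    of an interface when the patch shape is close to isotropic, and the pair
    must render as mutually aligned views for cognate samples to superimpose;
    transporting the axis makes the alignment exact for ideally opposed
    patches and degrades only with the tilt between the two planes.
    """
    coords = _patch_coordinates(patch, mode)
    if coords.shape[0] < 3:
        raise FrameError("need at least 3 points for a PCA frame")
    origin = coords.mean(axis=0)
    centred = coords - origin
    cov = centred.T @ centred
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 1e-9 * max(evals[2], 1.0):
        raise FrameError("patch coordinates are collinear or degenerate")
    n = evecs[:, 0]
    if n @ (patch.partner_centroid - origin) < 0:
        n = -n
    e1 = paratope_frame.e1 - (paratope_frame.e1 @ n) * n
    norm = np.linalg.norm(e1)
    if norm < 1e-6:   # planes orthogonal; fall back to the intrinsic rule
        return build_frame(patch, mode)
    e1 = e1 / norm
    e2 = np.cross(n, e1)
    return OrientedFrame(origin=origin, e1=e1, e2=e2, n=n)


def project(patch: InterfacePatch, frame: OrientedFrame,
            config: ImagingConfig) -> list[ProjectedPoint]:
    """Project patch members into the frame's plane coordinates."""
    points = []
    for res in patch.members:
        if config.mode == "residue":
            items = [(res.c_mu, _residue_radius(res.aa, config))]
        else:
            sc = res.side_chain_atoms()
            coords = [c for _, c in sc] if sc else [res.c_mu]
            items = [(c, config.atom_radius) for c in coords]
        for coord, radius in items:
            d = np.asarray(coord, dtype=float) - frame.origin
            points.append(ProjectedPoint(
                u=float(d @ frame.e1), v=float(d @ frame.e2),
                depth=float(abs(d @ frame.n)), aa=res.aa, radius=radius))
    return points


def _residue_radius(aa: str, config: ImagingConfig) -> float:
    try:
        return config.features.radius[aa]
    except KeyError:
        logger.warning("no radius for residue %r; using 2.5 A", aa)
        return 2.5


# ---------------------------------------------------------------------------
# colour and transparency
# ---------------------------------------------------------------------------

def colorize(aa: str, scheme: str = "PIH",
             knockout: tuple[str, ...] = (),
             config: ImagingConfig | None = None) -> tuple[float, float, float]:
    """RGB triple for an amino acid under the given colouring scheme."""
    if config is None:
        config = ImagingConfig()
    if scheme == "four_color":
        return FOUR_COLOR.get(aa, (1.0, 1.0, 1.0))
    if scheme != "PIH":
        raise ValueError(f"unknown colour scheme {scheme!r}")
    ft = config.features
    try:
        rgb = [ft.polarizability[aa], ft.isoelectric[aa], ft.hydrophobicity[aa]]
    except KeyError:
        logger.warning("unknown amino acid %r; using fallback colour", aa)
        return FALLBACK_COLOR
    for i, ch in enumerate("PIH"):
        if ch in knockout:
            rgb[i] = 0.0
    return tuple(rgb)


def alpha_from_depth(depth: float, d_max: float, alpha_min: float = 0.1,
                     enabled: bool = True) -> float:
    """Linear depth-to-opacity map, clamped to [alpha_min, 1]."""
    if not enabled:
        return 1.0
    if depth < 0 or d_max <= 0:
        raise ValueError("depth must be >= 0 and d_max > 0")
    return min(1.0, max(alpha_min, 1.0 - depth / d_max))


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

def _rotation(deg: float) -> np.ndarray:
    deg = deg % 360.0
    if deg == 0.0:
        return np.eye(2)
    th = math.radians(deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, -s], [s, c]])


def render(points: list[ProjectedPoint],
           colors: list[tuple[float, float, float]],
           alphas: list[float],
           size: int = 100, scale: float = 2.0,
           rotation_deg: float = 0.0,
           translation_A: tuple[float, float] = (0.0, 0.0)) -> PatchImage:
    """Rasterise projected points into a cropped square image.

    The canvas is 2*size pixels wide and centrally cropped to ``size``.
    Rotation (degrees, counter-clockwise) and translation (Angstrom) are
    applied to the (u, v) coordinates before rasterising; rotations compose by
    angle addition, so a 360-degree rotation is exactly the identity.

    Transformed coordinates are quantised to 1e-6 A and opacities to 1e-9
    before painting, so algebraically equivalent inputs (e.g. the same complex
    under a rigid motion) produce bit-identical images.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    canvas = 2 * size
    img = np.ones((canvas, canvas, 3), dtype=np.float64)
    R = _rotation(rotation_deg)
    du, dv = translation_A
    order = sorted(range(len(points)), key=lambda i: (-round(points[i].depth, 6), i))
    for i in order:
        p = points[i]
        u, v = R @ (p.u, p.v)
        u = round(u + du, 6)
        v = round(v + dv, 6)
        a = round(alphas[i], 9)
        col = u * scale + canvas / 2.0 - 0.5    # pixel-centre coordinates
        row = canvas / 2.0 - 0.5 - v * scale
        r_px = p.radius * scale
        if (col + r_px < 0 or col - r_px > canvas - 1
                or row + r_px < 0 or row - r_px > canvas - 1):
            logger.warning("point (%.1f, %.1f) falls outside the canvas; clipped", u, v)
            continue
        r0 = max(0, int(math.floor(row - r_px)))
        r1 = min(canvas - 1, int(math.ceil(row + r_px)))
        c0 = max(0, int(math.floor(col - r_px)))
        c1 = min(canvas - 1, int(math.ceil(col + r_px)))
        rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
        mask = (rr - row) ** 2 + (cc - col) ** 2 <= r_px ** 2
        tile = img[r0:r1 + 1, c0:c1 + 1]
        tile[mask] = (1.0 - a) * tile[mask] + a * np.asarray(colors[i])
    off = size // 2
    cropped = img[off:off + size, off:off + size]
    return PatchImage(pixels=cropped, side="", mode="", scale=scale,
                      angle=rotation_deg % 360.0)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def render_patch(patch: InterfacePatch, config: ImagingConfig,
                 mirror: bool = False, rotation_deg: float = 0.0,
                 translation_A: tuple[float, float] = (0.0, 0.0),
                 frame: OrientedFrame | None = None) -> PatchImage:
    """Project and rasterise one interface patch."""
    if frame is None:
        frame = build_frame(patch, config.mode)
    points = project(patch, frame, config)
    if mirror:
        for p in points:
            p.v = -p.v
    colors = [colorize(p.aa, config.scheme, config.knockout, config) for p in points]
    alphas = [alpha_from_depth(p.depth, config.d_max, config.alpha_min,
                               config.distance_feature) for p in points]
    image = render(points, colors, alphas, size=config.size, scale=config.scale,
                   rotation_deg=rotation_deg, translation_A=translation_A)
    image.side = patch.side
    image.mode = config.mode
    return image


def imagify_complex(record: ComplexRecord, config: ImagingConfig,
                    interface: InterfaceConfig | None = None,
                    epitope_rotation_deg: float = 0.0,
                    epitope_translation_A: tuple[float, float] = (0.0, 0.0),
                    ) -> tuple[PatchImage, PatchImage]:
    """Render the paratope and epitope images of a complex.

    Optional rotation/translation applies to the epitope image only (used by
    negative-sample generation and library screening).
    """
    if interface is None:
        interface = InterfaceConfig()
    paratope, epitope = find_interface(record, interface.cutoff, interface.cdr_radius)
    fp = build_frame(paratope, config.mode)
    fe = epitope_frame(fp, epitope, config.mode)
    para_img = render_patch(paratope, config, mirror=False, frame=fp)
    epi_img = render_patch(epitope, config, mirror=True,
                           rotation_deg=epitope_rotation_deg,
                           translation_A=epitope_translation_A, frame=fe)
    return para_img, epi_img


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def save_png(image: PatchImage, path: str) -> None:
    from PIL import Image
    arr = np.clip(np.rint(image.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def load_png(path: str) -> np.ndarray:
    from PIL import Image
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
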