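"""Synthetic coral-skeleton voxel geometry and pore-space bookkeeping.

Branching *Acropora* skeletons share a small set of structural motifs: a
rough outer surface with hemispherical bumps, a ring of radial corallite
cavities connecting the interior to the surface, a central axial channel
with gentle bending points, an enlarged apical corallite at the branch tip,
and occasionally a local defect where the wall has been breached.  The
generator here rasterizes those motifs into a labelled voxel volume so the
whole flow/dissolution chain can run at desk scale on a regular grid, in
place of a segmented micro-CT stack.

Label conventions
-----------------
Two schemes appear in practice and both are supported:

* 2-label (segmentation output): ``solid = 1``, ``pore = 2``.
* 3-label (canonical, used everywhere downstream): ``solid = 0``,
  ``inner pore = 1``, ``external pore = 2``.

:func:`label_inner_pores` converts the former into the latter by flood
filling the pore phase from the domain boundary (6-connectivity).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import ndimage

SOLID = 0
INNER_PORE = 1
EXTERNAL_PORE = 2

# 2-label scheme as produced by segmentation front-ends
SEG_SOLID = 1
SEG_PORE = 2


class GeometryParameterError(ValueError):
    """Raised when requested geometric features cannot fit the grid."""


@dataclass
class VoxelGeometry:
    """A labelled voxel volume with physical spacing.

    Parameters
    ----------
    labels
        3-D integer array over ``(nx, ny, nz)``; canonical labels are
        ``0`` solid, ``1`` inner pore, ``2`` external pore.
    spacing
        Voxel edge length in metres (cubic voxels).
    origin
        Physical coordinates of voxel ``(0, 0, 0)``.
    provenance
        Free text describing where the volume came from.
    """

    labels: np.ndarray
    spacing: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def solid_mask(self) -> np.ndarray:
        return self.labels == SOLID

    @property
    def pore_mask(self) -> np.ndarray:
        return self.labels != SOLID

    @property
    def inner_pore_mask(self) -> np.ndarray:
        return self.labels == INNER_PORE

    def count(self, label: int) -> int:
        """Exact voxel count of one label."""
        return int(np.count_nonzero(self.labels == label))

    def inner_pore_volume(self) -> float:
        """Physical inner-pore volume in m^3."""
        return self.count(INNER_PORE) * self.spacing**3

    def copy(self) -> "VoxelGeometry":
        return dataclasses.replace(self, labels=self.labels.copy())


@dataclass
class RegionSelection:
    """A named sub-region of the grid: an axis-aligned box or a mask.

    ``box`` is ``((x0, x1), (y0, y1), (z0, z1))`` with half-open bounds in
    voxel indices; alternatively supply a boolean ``mask`` on the full grid.
    """

    name: str
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None
    mask: np.ndarray | None = None

    def select(self, array: np.ndarray) -> np.ndarray:
        """Values of ``array`` inside the region (flattened for masks)."""
        if self.mask is not None:
            return array[self.mask]
        (x0, x1), (y0, y1), (z0, z1) = self.box
        return array[x0:x1, y0:y1, z0:z1]

    def mask_on(self, shape: tuple[int, int, int]) -> np.ndarray:
        if self.mask is not None:
            return self.mask
        m = np.zeros(shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = self.box
        m[x0:x1, y0:y1, z0:z1] = True
        return m


@dataclass
class CoralParams:
    """Parameters of the synthetic branching-coral generator.

    Defaults rasterize a branch with the proportions of a ~4 cm tall,
    ~1.2 cm wide *Acropora* sample onto a 64x64x128 grid (flow along x,
    growth axis along z): `spacing` maps the 28-voxel branch diameter to
    1.2 cm.  All length-like fields are in voxels.
    """

    shape: tuple[int, int, int] = (64, 64, 128)
    cylinder_radius: float = 14.0
    cylinder_height: int = 96
    channel_radius: float = 4.0
    n_bends: int = 3
    bend_amplitude: float = 2.0
    n_corallites: int = 12
    corallite_radius: float = 2.5
    bump_amplitude: float = 2.5
    apical_radius: float = 6.0
    defect: bool = False
    defect_radius: float = 3.5
    defect_height_frac: float = 0.8
    seal_openings: bool = False
    spacing: float = 0.012 / 28.0
    seed: int = 0

    def validate(self) -> None:
        nx, ny, nz = self.shape
        r = self.cylinder_radius
        if self.channel_radius >= r:
            raise GeometryParameterError("channel radius must be < cylinder radius")
        if 2 * (r + self.bump_amplitude) >= min(nx, ny):
            raise GeometryParameterError("cylinder + bumps do not fit the grid laterally")
        if self.cylinder_height + self.apical_radius >= nz:
            raise GeometryParameterError("cylinder + apex do not fit the grid vertically")
        if self.cylinder_height <= 0 or r <= 0:
            raise GeometryParameterError("cylinder dimensions must be positive")


def _channel_centerline(params: CoralParams, rng: np.random.Generator) -> np.ndarray:
    """(nz, 2) lateral (x, y) centre of the axial channel per z-layer.

    Piecewise linear between ``n_bends`` interior inflection points with
    lateral offsets of magnitude ``bend_amplitude``.
    """
    nx, ny, nz = params.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    h = params.cylinder_height
    zs = [0]
    for k in range(params.n_bends):
        zs.append(int(round((k + 1) * h / (params.n_bends + 1))))
    zs.append(h)
    offsets = [np.zeros(2)]
    for _ in range(params.n_bends):
        theta = rng.uniform(0, 2 * np.pi)
        offsets.append(params.bend_amplitude * np.array([np.cos(theta), np.sin(theta)]))
    offsets.append(np.zeros(2))
    line = np.zeros((nz, 2))
    line[:, 0], line[:, 1] = cx, cy
    for (z0, o0), (z1, o1) in zip(zip(zs[:-1], offsets[:-1]), zip(zs[1:], offsets[1:])):
        if z1 <= z0:
            continue
        t = np.linspace(0.0, 1.0, z1 - z0, endpoint=False)[:, None]
        line[z0:z1] = np.array([cx, cy]) + (1 - t) * o0 + t * o1
    return line


def generate_coral(params: CoralParams) -> VoxelGeometry:
    """Rasterize a synthetic coral branch and return the canonical volume.

    The branch is a vertical porous cylinder standing on the bottom face
    (the seabed): a central axial channel (optionally bent), radial
    corallite cavities spiralling from the channel to the surface, solid
    hemispherical bumps at the cavity mouths, an apical corallite opening
    at the tip, and an optional through-wall defect.  Voxels are included
    by centre-of-voxel tests, so all counts are exact integers.
    Deterministic for a fixed seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    nx, ny, nz = params.shape
    X, Y, Z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    h = params.cylinder_height

    solid = ((X - cx) ** 2 + (Y - cy) ** 2 <= params.cylinder_radius**2) & (Z < h)

    # surface bumps and corallite mouths share locations (spiral placement)
    thetas = np.sort(rng.uniform(0, 2 * np.pi, params.n_corallites))
    if params.n_corallites > 0:
        z_cor = np.linspace(0.15 * h, 0.85 * h, params.n_corallites)
        z_cor = z_cor + rng.uniform(-2, 2, params.n_corallites)
    else:
        z_cor = np.empty(0)

    for theta, zc in zip(thetas, z_cor):
        mx = cx + params.cylinder_radius * np.cos(theta)
        my = cy + params.cylinder_radius * np.sin(theta)
        if params.bump_amplitude > 0:
            bump = (X - mx) ** 2 + (Y - my) ** 2 + (Z - zc) ** 2 <= params.bump_amplitude**2
            solid |= bump

    carve = np.zeros_like(solid)

    # axial channel along the (bent) centerline
    line = _channel_centerline(params, rng)
    z0_ch = max(2, int(0.04 * h))
    for z in range(z0_ch, h):
        lx, ly = line[z]
        carve[:, :, z] |= (X[:, :, z] - lx) ** 2 + (Y[:, :, z] - ly) ** 2 <= params.channel_radius**2

    # apical corallite: enlarged cavity at the tip, opening the channel upward
    if params.apical_radius > 0:
        lx, ly = line[min(h, nz - 1) - 1]
        apex = (X - lx) ** 2 + (Y - ly) ** 2 + (Z - h) ** 2 <= params.apical_radius**2
        carve |= apex

    # radial corallites: cylindrical tunnels channel -> surface
    for theta, zc in zip(thetas, z_cor):
        lx, ly = line[int(np.clip(round(zc), 0, nz - 1))]
        d = np.array([np.cos(theta), np.sin(theta)])
        # tunnel from channel axis out past the bump
        length = params.cylinder_radius + params.bump_amplitude + 1.0
        px = X - lx
        py = Y - ly
        t = px * d[0] + py * d[1]
        perp2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (Z - zc) ** 2
        carve |= (t >= 0) & (t <= length) & (perp2 <= params.corallite_radius**2)

    # local defect: horizontal through-wall hole high on the branch
    if params.defect:
        zd = params.defect_height_frac * h
        theta = float(rng.uniform(0, 2 * np.pi))
        d = np.array([np.cos(theta), np.sin(theta)])
        px = X - cx
        py = Y - cy
        t = px * d[0] + py * d[1]
        perp2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (Z - zd) ** 2
        carve |= (t >= 0) & (t <= params.cylinder_radius + params.bump_amplitude + 1.0) & (
            perp2 <= params.defect_radius**2
        )

    solid &= ~carve
    if params.seal_openings:
        # cap every pore voxel on the cylinder's outer shell so the interior
        # is strictly sealed (used to exercise the inner/external distinction)
        shell = (
            ((X - cx) ** 2 + (Y - cy) ** 2 <= params.cylinder_radius**2)
            & ((X - cx) ** 2 + (Y - cy) ** 2 > (params.cylinder_radius - 1.5) ** 2)
            & (Z < h)
        )
        cap = (
            ((X - cx) ** 2 + (Y - cy) ** 2 <= params.cylinder_radius**2)
            & (Z >= h - 2) & (Z < h + 2)
        )
        solid |= shell | cap

    # the generator knows its own envelope exactly: pore voxels inside the
    # nominal cylinder are the skeleton's interior (inner pores), everything
    # else is the ambient external pore space.  The apex/corallite mouths are
    # the declared skeleton openings through which the interior connects out.
    envelope = ((X - cx) ** 2 + (Y - cy) ** 2 <= params.cylinder_radius**2) & (Z < h)
    labels = np.full(params.shape, EXTERNAL_PORE, dtype=np.uint8)
    labels[solid] = SOLID
    labels[~solid & envelope] = INNER_PORE
    return VoxelGeometry(
        labels=labels,
        spacing=params.spacing,
        provenance=f"synthetic coral {dataclasses.asdict(params)}",
    )


def label_inner_pores(
    geometry: VoxelGeometry,
    cap_openings: bool = False,
    closing_radius: int = 4,
) -> VoxelGeometry:
    """Split the pore phase into external and inner pores (canonical labels).

    Pore voxels reachable from any face of the bounding box through
    face-connected (6-connectivity) pore paths become external (2); the
    rest become inner (1); solid becomes 0.  Accepts either the 2-label
    segmentation scheme or an already-canonical volume (idempotent).

    With ``cap_openings=True`` the solid phase is first morphologically
    closed with a ball of ``closing_radius`` voxels, sealing pore mouths
    narrower than the ball, so a channel that opens to the outside is
    still counted as interior pore space.  The closed envelope only
    steers the reachability test; the returned solid phase is unchanged.
    """
    labels = geometry.labels
    values = set(np.unique(labels).tolist())
    if values <= {SEG_SOLID, SEG_PORE} and SEG_SOLID in values:
        pore = labels == SEG_PORE
        solid = labels == SEG_SOLID
    else:
        pore = labels != SOLID
        solid = labels == SOLID

    if not pore.any():
        warnings.warn("volume contains no pore voxels; returning all-solid volume")
        out = np.zeros_like(labels, dtype=np.uint8)
        return dataclasses.replace(geometry, labels=out)

    reachable_space = pore
    if cap_openings:
        r = int(closing_radius)
        zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
        ball = xx**2 + yy**2 + zz**2 <= r**2
        closed = ndimage.binary_closing(solid, structure=ball)
        reachable_space = pore & ~closed

    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    comp, n = ndimage.label(reachable_space, structure=structure)
    boundary_ids = np.unique(
        np.concatenate(
            [
                comp[0].ravel(), comp[-1].ravel(),
                comp[:, 0].ravel(), comp[:, -1].ravel(),
                comp[:, :, 0].ravel(), comp[:, :, -1].ravel(),
            ]
        )
    )
    boundary_ids = boundary_ids[boundary_ids > 0]
    external = np.isin(comp, boundary_ids)
    out = np.zeros_like(labels, dtype=np.uint8)
    out[pore & external] = EXTERNAL_PORE
    out[pore & ~external] = INNER_PORE
    return dataclasses.replace(geometry, labels=out)


def porosity(
    geometry: VoxelGeometry,
    region: RegionSelection | None = None,
    filled_reference: VoxelGeometry | None = None,
) -> float:
    """Pore/solid porosity ratio.

    With ``filled_reference`` (a volume whose internal pores are closed,
    see :func:`fill_internal_pores`) the whole-sample variant
    ``n = (pores(sample) - pores(filled)) / solid(sample)`` is computed —
    the difference isolates the internal pore voxels.  Without it, the
    region variant ``n = pores(region) / solid(region)`` is returned.
    Both are ratios to the *solid* count and may exceed 1 when pores
    outnumber solid.  Counts are exact integers before division.
    """
    if filled_reference is not None:
        pores_whole = int(np.count_nonzero(geometry.labels != SOLID))
        pores_filled = int(np.count_nonzero(filled_reference.labels != SOLID))
        solid = int(np.count_nonzero(geometry.labels == SOLID))
        if solid == 0:
            raise ZeroDivisionError("no solid voxels in sample")
        return (pores_whole - pores_filled) / solid
    labels = region.select(geometry.labels) if region is not None else geometry.labels
    pores = int(np.count_nonzero(labels != SOLID))
    solid = int(np.count_nonzero(labels == SOLID))
    if solid == 0:
        raise ZeroDivisionError("no solid voxels in region")
    return pores / solid


def porosity_fraction(geometry: VoxelGeometry, region: RegionSelection | None = None) -> float:
    """Conventional porosity: pore voxels / total voxels, in [0, 1]."""
    labels = region.select(geometry.labels) if region is not None else geometry.labels
    return int(np.count_nonzero(labels != SOLID)) / labels.size


def fill_internal_pores(geometry: VoxelGeometry) -> VoxelGeometry:
    """Close the inner pore space (inner pores -> solid); external untouched."""
    out = geometry.labels.copy()
    out[out == INNER_PORE] = SOLID
    return dataclasses.replace(geometry, labels=out)


def rotate_half_turn(geometry: VoxelGeometry) -> VoxelGeometry:
    """Rotate the volume 180 degrees about the vertical (z) axis."""
    return dataclasses.replace(geometry, labels=geometry.labels[::-1, ::-1, :].copy())


def downsample(geometry: VoxelGeometry, factor: int) -> VoxelGeometry:
    """Block-reduce by ``factor`` with majority vote, ties going to solid.

    Solid preference on ties keeps thin walls connected, which matters for
    the inner/external pore distinction downstream.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    labels = geometry.labels
    nx, ny, nz = (s // factor for s in labels.shape)
    trimmed = labels[: nx * factor, : ny * factor, : nz * factor]
    blocks = trimmed.reshape(nx, factor, ny, factor, nz, factor)
    blocks = blocks.transpose(0, 2, 4, 1, 3, 5).reshape(nx, ny, nz, factor**3)
    counts = np.stack([(blocks == v).sum(axis=-1) for v in (SOLID, INNER_PORE, EXTERNAL_PORE)], axis=-1)
    # argmax with index order (solid first) implements the solid-preference tie-break
    out = np.argmax(counts, axis=-1).astype(np.uint8)
    return dataclasses.replace(
        geometry, labels=out, spacing=geometry.spacing * factor,
        provenance=geometry.provenance + f" | downsampled x{factor}",
    )
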