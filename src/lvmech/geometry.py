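"""Idealized left-ventricular geometry: hexahedral meshing, septum detection,
AHA 17-sector partition, rule-based fibers and cavity volume.

The computational domain is a truncated prolate spheroid standing in for a
patient-specific LV: endocardial and epicardial ellipsoids share a center on
the long axis (aligned with z), the base plane is z = 0 and the apex points
toward negative z.  The wall is meshed with a structured grid of trilinear
hexahedra (transmural x circumferential x longitudinal) closed at the apex by
a butterfly (O-grid) cap that avoids collapsed nodes at the pole.

All lengths are millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IdealizedGeometry",
    "MeshDensity",
    "HexMesh",
    "MeshQualityError",
    "generate_idealized_lv",
    "make_rv_endo_shell",
    "detect_septum",
    "septal_wedge_facets",
    "partition_aha17",
    "assign_fibers",
    "cavity_volume",
]


class MeshQualityError(RuntimeError):
    """Raised when generated elements have non-positive Jacobians."""


@dataclass(frozen=True)
class IdealizedGeometry:
    """Truncated prolate-spheroid LV wall.

    Parameters
    ----------
    a_endo, c_endo:
        Endocardial short/long semi-axes (mm).
    wall_thickness:
        Wall thickness at the equator (mm); added to ``a_endo`` radially.
    apex_thickness:
        Wall thickness at the apex (mm); added to ``c_endo`` along the axis.
    truncation:
        Height of the base plane above the ellipsoid equator as a fraction of
        ``c_endo``.  0 truncates at the equator (half ellipsoid), 0.5 keeps
        half of the upper hemisphere.
    """

    a_endo: float = 20.0
    c_endo: float = 50.0
    wall_thickness: float = 10.0
    apex_thickness: float = 6.0
    truncation: float = 0.5

    def __post_init__(self) -> None:
        if min(self.a_endo, self.c_endo, self.wall_thickness, self.apex_thickness) <= 0:
            raise ValueError("all geometric dimensions must be positive")
        if not 0.0 <= self.truncation < 1.0:
            raise ValueError("truncation fraction must lie in [0, 1)")

    @property
    def a_epi(self) -> float:
        return self.a_endo + self.wall_thickness

    @property
    def c_epi(self) -> float:
        return self.c_endo + self.apex_thickness

    @property
    def z_center(self) -> float:
        """z of the shared ellipsoid center (base plane is z = 0)."""
        return -self.truncation * self.c_endo


@dataclass(frozen=True)
class MeshDensity:
    """Structured element counts: transmural, circumferential, longitudinal."""

    n_transmural: int = 2
    n_circumferential: int = 12
    n_longitudinal: int = 6

    def __post_init__(self) -> None:
        if min(self.n_transmural, self.n_circumferential, self.n_longitudinal) < 1:
            raise ValueError("element counts must be positive")
        if self.n_circumferential % 4:
            raise ValueError("n_circumferential must be divisible by 4 (apex cap)")

    @property
    def n_body(self) -> int:
        return self.n_transmural * self.n_circumferential * self.n_longitudinal

    @property
    def n_cap(self) -> int:
        m = self.n_circumferential // 4
        return self.n_transmural * m * m

    @property
    def n_elements(self) -> int:
        return self.n_body + self.n_cap


@dataclass
class HexMesh:
    """Hexahedral LV mesh with surface facet sets and per-element metadata.

    ``facet_sets`` maps ``endo``/``epi``/``base`` (and, after septum
    detection, ``septal_epi``) to (K, 4) node-index quads ordered so their
    right-hand normal points out of the solid wall.  ``element_sector`` holds
    AHA labels 1-17 (0 = unassigned).  ``element_frame_*`` are the local
    cardiac directions (circumferential, longitudinal, radial) per element and
    ``fiber_vector`` the per-element myofiber direction once assigned.
    """

    nodes: np.ndarray
    elements: np.ndarray
    facet_sets: dict[str, np.ndarray]
    element_sector: np.ndarray
    element_frame_c: np.ndarray | None = None
    element_frame_l: np.ndarray | None = None
    element_frame_r: np.ndarray | None = None
    fiber_vector: np.ndarray | None = None
    # structured-grid metadata used by fibers / mechanics
    element_layer: np.ndarray | None = None      # transmural layer index (0 = endo)
    n_transmural: int = 0
    is_cap: np.ndarray | None = None
    geometry: IdealizedGeometry | None = None
    density: MeshDensity | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def jacobians(self) -> np.ndarray:
        """det of the isoparametric map at the 8 Gauss points, (E, 8)."""
        from . import _fem

        dN = _fem.shape_gradients()
        J = np.einsum("gai,eaj->egij", dN, self.nodes[self.elements])
        return np.linalg.det(J)

    def check_quality(self) -> None:
        det = self.jacobians()
        if det.min() <= 0.0:
            bad = np.unique(np.where(det <= 0)[0])
            raise MeshQualityError(
                f"{len(bad)} element(s) with non-positive Jacobian, e.g. {bad[:5]}"
            )


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------

def _surface_point(a: float, c: float, zc: float, u: np.ndarray, theta: np.ndarray):
    """Point on an ellipsoid parametrized by colatitude u (0 = +z pole)."""
    r = a * np.sin(u)
    return np.stack(
        [r * np.cos(theta), r * np.sin(theta), zc + c * np.cos(u)], axis=-1
    )


def _disk_grid(m: int) -> tuple[np.ndarray, np.ndarray]:
    """Map an (m+1)x(m+1) grid on [-1,1]^2 to the unit disk.

    Uses the elliptical square-to-disk map followed by an angular remap that
    makes the boundary nodes uniformly spaced in azimuth (so they can be
    identified with the circumferential ring of the body mesh).  Returns the
    (x, y) arrays of shape (m+1, m+1).
    """
    s = np.linspace(-1.0, 1.0, m + 1)
    u, v = np.meshgrid(s, s, indexing="ij")
    x = u * np.sqrt(np.maximum(1.0 - 0.5 * v * v, 0.0))
    y = v * np.sqrt(np.maximum(1.0 - 0.5 * u * u, 0.0))
    r = np.hypot(x, y)
    phi = np.arctan2(y, x)
    # boundary angles of the elliptical map follow phi = k*90deg + asin(t/sqrt2)
    # with t in [-1,1] the edge parameter; invert that so they become uniform.
    quad = np.round(phi / (0.5 * np.pi))
    local = phi - quad * 0.5 * np.pi
    phi_new = quad * 0.5 * np.pi + 0.25 * np.pi * np.sqrt(2.0) * np.sin(local)
    return r * np.cos(phi_new), r * np.sin(phi_new)


def generate_idealized_lv(geom: IdealizedGeometry, density: MeshDensity) -> HexMesh:
    """Mesh the truncated prolate-spheroid wall with hex8 elements.

    The body is a structured (n_t, n_c, n_l) grid between the endo- and
    epicardial ellipsoids; the apical hole is closed by a butterfly cap of
    (n_c/4)^2 x n_t hexahedra whose boundary nodes coincide with the last
    circumferential ring.  Facet sets ``endo``/``epi``/``base`` are populated;
    sector labels are left unassigned.
    """
    nt, nc, nl = density.n_transmural, density.n_circumferential, density.n_longitudinal
    m = nc // 4
    zc = geom.z_center

    u_base_en = np.arccos(np.clip(geom.truncation * geom.c_endo / geom.c_endo, -1, 1))
    u_base_ep = np.arccos(np.clip(geom.truncation * geom.c_endo / geom.c_epi, -1, 1))
    # fraction of the latitude span handed to the apex cap: about m elements'
    # worth so cap and body element sizes are comparable
    cap_frac = m / (nl + m)
    theta = np.arange(nc) * (2.0 * np.pi / nc)
    # longitudinal node parameter s in [0, 1] over the body (0 = base, 1 = cap rim)
    s_long = np.linspace(0.0, 1.0, nl + 1)
    t_trans = np.linspace(0.0, 1.0, nt + 1)

    def shell_nodes(s: np.ndarray, th: np.ndarray, t: float) -> np.ndarray:
        """Transmural interpolation between endo and epi at parameters (s, th)."""
        u_en = u_base_en + s * (np.pi - u_base_en) * (1.0 - cap_frac)
        u_ep = u_base_ep + s * (np.pi - u_base_ep) * (1.0 - cap_frac)
        p_en = _surface_point(geom.a_endo, geom.c_endo, zc, u_en, th)
        p_ep = _surface_point(geom.a_epi, geom.c_epi, zc, u_ep, th)
        return (1.0 - t) * p_en + t * p_ep

    ss, tt = np.meshgrid(s_long, theta, indexing="ij")  # (nl+1, nc)
    body_nodes = np.empty((nt + 1, nl + 1, nc, 3))
    for k, t in enumerate(t_trans):
        body_nodes[k] = shell_nodes(ss, tt, t)
    body_nodes[:, 0, :, 2] = 0.0  # base ring exactly on the truncation plane

    def body_id(k: int | np.ndarray, i: int | np.ndarray, j: int | np.ndarray):
        return (np.asarray(k) * (nl + 1) + np.asarray(i)) * nc + np.asarray(j) % nc

    nodes = [body_nodes.reshape(-1, 3)]
    next_id = (nt + 1) * (nl + 1) * nc

    # ---- apex cap nodes -------------------------------------------------
    dx, dy = _disk_grid(m)
    rho = np.hypot(dx, dy)
    phi = np.arctan2(dy, dx)
    if m % 2:  # boundary angles offset by half a step; rotate onto the ring
        phi = phi + np.pi / nc
    on_boundary = (
        np.isclose(abs(np.linspace(-1, 1, m + 1)), 1.0)[:, None]
        | np.isclose(abs(np.linspace(-1, 1, m + 1)), 1.0)[None, :]
    )

    u_cut_en = u_base_en + (np.pi - u_base_en) * (1.0 - cap_frac)
    u_cut_ep = u_base_ep + (np.pi - u_base_ep) * (1.0 - cap_frac)
    r_cut_en = geom.a_endo * np.sin(u_cut_en)
    r_cut_ep = geom.a_epi * np.sin(u_cut_ep)

    cap_ids = np.full((nt + 1, m + 1, m + 1), -1, dtype=int)
    cap_nodes: list[np.ndarray] = []
    dtheta = 2.0 * np.pi / nc
    for k, t in enumerate(t_trans):
        for p in range(m + 1):
            for q in range(m + 1):
                if on_boundary[p, q]:
                    j = int(np.round(phi[p, q] / dtheta)) % nc
                    cap_ids[k, p, q] = body_id(k, nl, j)
                else:
                    r_en = rho[p, q] * r_cut_en
                    r_ep = rho[p, q] * r_cut_ep
                    z_en = zc - geom.c_endo * np.sqrt(
                        max(1.0 - (r_en / geom.a_endo) ** 2, 0.0)
                    )
                    z_ep = zc - geom.c_epi * np.sqrt(
                        max(1.0 - (r_ep / geom.a_epi) ** 2, 0.0)
                    )
                    r_t = (1 - t) * r_en + t * r_ep
                    z_t = (1 - t) * z_en + t * z_ep
                    cap_nodes.append(
                        np.array(
                            [r_t * np.cos(phi[p, q]), r_t * np.sin(phi[p, q]), z_t]
                        )
                    )
                    cap_ids[k, p, q] = next_id
                    next_id += 1
    if cap_nodes:
        nodes.append(np.array(cap_nodes))
    all_nodes = np.concatenate(nodes, axis=0)

    # ---- elements -------------------------------------------------------
    # local node ordering: bottom face (endo side, counter-clockwise about the
    # outward transmural axis), then top face; zeta = transmural axis.
    elems, layer, cap_flag = [], [], []
    for k in range(nt):
        for i in range(nl):
            for j in range(nc):
                n0 = body_id(k, i, j)
                n1 = body_id(k, i, j + 1)
                n2 = body_id(k, i + 1, j + 1)
                n3 = body_id(k, i + 1, j)
                n4 = body_id(k + 1, i, j)
                n5 = body_id(k + 1, i, j + 1)
                n6 = body_id(k + 1, i + 1, j + 1)
                n7 = body_id(k + 1, i + 1, j)
                elems.append([n0, n1, n2, n3, n4, n5, n6, n7])
                layer.append(k)
                cap_flag.append(False)
    for k in range(nt):
        for p in range(m):
            for q in range(m):
                c00 = cap_ids[k, p, q]
                c10 = cap_ids[k, p + 1, q]
                c11 = cap_ids[k, p + 1, q + 1]
                c01 = cap_ids[k, p, q + 1]
                d00 = cap_ids[k + 1, p, q]
                d10 = cap_ids[k + 1, p + 1, q]
                d11 = cap_ids[k + 1, p + 1, q + 1]
                d01 = cap_ids[k + 1, p, q + 1]
                elems.append([c00, c10, c11, c01, d00, d10, d11, d01])
                layer.append(k)
                cap_flag.append(True)
    elements = np.array(elems, dtype=int)

    # fix cap orientation if the disk grid happens to be left-handed
    from . import _fem

    dN = _fem.shape_gradients()
    det = np.linalg.det(np.einsum("gai,eaj->egij", dN, all_nodes[elements]))
    flip = det.mean(axis=1) < 0
    if flip.any():
        elements[flip] = elements[flip][:, [1, 0, 3, 2, 5, 4, 7, 6]]

    # ---- facet sets -----------------------------------------------------
    endo, epi, base = [], [], []
    for i in range(nl):
        for j in range(nc):
            # endo facet of body layer 0, normal pointing into the cavity
            endo.append(
                [body_id(0, i, j), body_id(0, i + 1, j),
                 body_id(0, i + 1, j + 1), body_id(0, i, j + 1)]
            )
            epi.append(
                [body_id(nt, i, j), body_id(nt, i, j + 1),
                 body_id(nt, i + 1, j + 1), body_id(nt, i + 1, j)]
            )
    for p in range(m):
        for q in range(m):
            endo.append(
                [cap_ids[0, p, q], cap_ids[0, p + 1, q],
                 cap_ids[0, p + 1, q + 1], cap_ids[0, p, q + 1]]
            )
            epi.append(
                [cap_ids[nt, p, q], cap_ids[nt, p, q + 1],
                 cap_ids[nt, p + 1, q + 1], cap_ids[nt, p + 1, q]]
            )
    for k in range(nt):
        for j in range(nc):
            base.append(
                [body_id(k, 0, j), body_id(k, 0, j + 1),
                 body_id(k + 1, 0, j + 1), body_id(k + 1, 0, j)]
            )

    def orient_outward(quads: np.ndarray, direction: str) -> np.ndarray:
        """Flip quads so the right-hand normal points out of the solid."""
        pts = all_nodes[quads]
        cen = pts.mean(axis=1)
        nrm = np.cross(pts[:, 2] - pts[:, 0], pts[:, 3] - pts[:, 1])
        if direction == "base":
            want = np.tile([0.0, 0.0, 1.0], (len(quads), 1))
        else:
            radial = cen.copy()
            radial[:, 2] = cen[:, 2] - zc  # away from the ellipsoid center
            want = radial if direction == "out" else -radial
        wrong = np.einsum("ki,ki->k", nrm, want) < 0
        quads[wrong] = quads[wrong][:, ::-1]
        return quads

    facet_sets = {
        "endo": orient_outward(np.array(endo, dtype=int), "in"),
        "epi": orient_outward(np.array(epi, dtype=int), "out"),
        "base": orient_outward(np.array(base, dtype=int), "base"),
    }

    mesh = HexMesh(
        nodes=all_nodes,
        elements=elements,
        facet_sets=facet_sets,
        element_sector=np.zeros(len(elements), dtype=int),
        element_layer=np.array(layer, dtype=int),
        n_transmural=nt,
        is_cap=np.array(cap_flag, dtype=bool),
        geometry=geom,
        density=density,
    )
    mesh.check_quality()
    _compute_frames(mesh)
    return mesh


def _compute_frames(mesh: HexMesh) -> None:
    """Local cardiac triads per element.

    e_r is the outward transmural direction (mean of the four transmural
    element edges, endo -> epi), e_l the projection of +z onto the plane
    normal to e_r, and e_c = e_l x e_r, which makes (e_c, e_l, e_r)
    right-handed.  Near the apex pole, where +z degenerates, +x seeds e_l.
    """
    pts = mesh.nodes[mesh.elements]
    e_r = (pts[:, 4:8].mean(axis=1) - pts[:, 0:4].mean(axis=1))
    e_r /= np.linalg.norm(e_r, axis=1, keepdims=True)
    zhat = np.array([0.0, 0.0, 1.0])
    e_l = zhat - e_r * (e_r @ zhat)[:, None]
    nl = np.linalg.norm(e_l, axis=1)
    bad = nl < 0.1
    if bad.any():
        xhat = np.array([1.0, 0.0, 0.0])
        alt = xhat - e_r[bad] * (e_r[bad] @ xhat)[:, None]
        e_l[bad] = alt
        nl = np.linalg.norm(e_l, axis=1)
    e_l /= nl[:, None]
    e_c = np.cross(e_l, e_r)
    mesh.element_frame_c, mesh.element_frame_l, mesh.element_frame_r = e_c, e_l, e_r


# ---------------------------------------------------------------------------
# septum
# ---------------------------------------------------------------------------

def make_rv_endo_shell(
    geom: IdealizedGeometry,
    azimuth: tuple[float, float] = (120.0, 240.0),
    gap: float = 2.0,
    n_theta: int = 16,
    n_z: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic RV endocardial half-shell hugging the LV epicardium.

    A partial cylinder of radius ``a_epi + gap`` spanning the given azimuth
    wedge (degrees, counter-clockwise from +x) over most of the long axis.
    Returns (vertices, triangles) for use with :func:`detect_septum`.
    """
    th = np.radians(np.linspace(azimuth[0], azimuth[1], n_theta + 1))
    z = np.linspace(-0.85 * (geom.truncation + 1.0) * geom.c_endo, -1.0, n_z + 1)
    r = geom.a_epi + gap
    tg, zg = np.meshgrid(th, z, indexing="ij")
    verts = np.stack([r * np.cos(tg), r * np.sin(tg), zg], axis=-1).reshape(-1, 3)
    tris = []
    for i in range(n_theta):
        for j in range(n_z):
            a = i * (n_z + 1) + j
            b = (i + 1) * (n_z + 1) + j
            tris.append([a, b, b + 1])
            tris.append([a, b + 1, a + 1])
    return verts, np.array(tris, dtype=int)


def _facet_centroids_normals(mesh: HexMesh, name: str):
    quads = mesh.facet_sets[name]
    pts = mesh.nodes[quads]
    cen = pts.mean(axis=1)
    nrm = 0.5 * np.cross(pts[:, 2] - pts[:, 0], pts[:, 3] - pts[:, 1])
    nrm = nrm / np.linalg.norm(nrm, axis=1, keepdims=True)
    return cen, nrm


def _ray_triangle_distances(
    origins: np.ndarray, directions: np.ndarray,
    verts: np.ndarray, faces: np.ndarray,
) -> np.ndarray:
    """Forward hit distance per ray against a triangle soup (inf = miss).

    Vectorized Moller-Trumbore over all (ray, triangle) pairs; fine at the
    problem sizes here (hundreds of facets x hundreds of triangles).
    """
    v0 = verts[faces[:, 0]]
    e1 = verts[faces[:, 1]] - v0
    e2 = verts[faces[:, 2]] - v0
    eps = 1e-12
    p = np.cross(directions[:, None, :], e2[None, :, :])      # (R,T,3)
    det = np.einsum("rti,ti->rt", p, e1)
    ok = np.abs(det) > eps
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origins[:, None, :] - v0[None, :, :]
    u = np.einsum("rti,rti->rt", tvec, p) * inv_det
    q = np.cross(tvec, e1[None, :, :])
    v = np.einsum("rti,ri->rt", q, directions) * inv_det
    t = np.einsum("rti,ti->rt", q, e2) * inv_det
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1.0 + eps) & (t > eps)
    t = np.where(hit, t, np.inf)
    return t.min(axis=1)


def detect_septum(
    mesh: HexMesh,
    rv_surface: tuple[np.ndarray, np.ndarray],
    max_distance: float = 10.0,
) -> np.ndarray:
    """Locate septal epicardial facets by ray casting against the RV surface.

    Casts a ray from each epicardial facet centroid along its outward normal;
    facets whose ray hits the RV endocardial triangle surface within
    ``max_distance`` (mm) form the septum.  The result is stored as facet set
    ``septal_epi`` and the indices (into the ``epi`` facet set) are returned.
    """
    verts, faces = rv_surface
    if len(faces) == 0 or len(verts) == 0:
        raise ValueError(
            "empty RV surface: use septal_wedge_facets() for the angular-wedge fallback"
        )
    cen, nrm = _facet_centroids_normals(mesh, "epi")
    dist = _ray_triangle_distances(cen, nrm, np.asarray(verts, float),
                                   np.asarray(faces, int))
    idx = np.where(dist <= max_distance)[0]
    mesh.facet_sets["septal_epi"] = mesh.facet_sets["epi"][idx]
    return idx


def septal_wedge_facets(
    mesh: HexMesh, wedge: tuple[float, float] = (120.0, 240.0)
) -> np.ndarray:
    """Fallback septum: epicardial facets whose centroid azimuth lies in the
    wedge (degrees CCW from +x, e.g. (120, 240) = +-60 deg about -x)."""
    cen, _ = _facet_centroids_normals(mesh, "epi")
    az = np.degrees(np.arctan2(cen[:, 1], cen[:, 0])) % 360.0
    lo, hi = wedge[0] % 360.0, wedge[1] % 360.0
    inside = (az >= lo) & (az <= hi) if lo <= hi else (az >= lo) | (az <= hi)
    idx = np.where(inside)[0]
    mesh.facet_sets["septal_epi"] = mesh.facet_sets["epi"][idx]
    return idx


# ---------------------------------------------------------------------------
# AHA 17-sector partition
# ---------------------------------------------------------------------------

def _circular_span(angles_deg: np.ndarray) -> tuple[float, float]:
    """Center and half-width (deg) of a set of azimuths on the circle."""
    rad = np.radians(angles_deg)
    center = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0
    dev = (angles_deg - center + 180.0) % 360.0 - 180.0
    return center, float(np.abs(dev).max())


def _ring_sector(psi_e: np.ndarray, n_sec: int, offset_deg: float,
                 base_label: int) -> np.ndarray:
    """Circumferential wedge labels for one longitudinal ring.

    psi advances from the anterior insertion across the septum; wedge k
    carries label base+1+((k+1) mod n), making the first wedge past the
    insertion the first *septal* sector (2, 8 or 14).  A value exactly on a
    wedge boundary takes the lower-numbered neighbor.
    """
    width = 360.0 / n_sec
    x = ((np.asarray(psi_e, dtype=float) - offset_deg) % 360.0) / width
    k = np.floor(x).astype(int) % n_sec
    labels = base_label + 1 + (k + 1) % n_sec
    on_boundary = np.abs(x - np.round(x)) < 1e-9
    if on_boundary.any():
        kr = np.round(x[on_boundary]).astype(int)
        la = base_label + 1 + (kr % n_sec + 1) % n_sec
        lb = base_label + 1 + ((kr - 1) % n_sec + 1) % n_sec
        labels[on_boundary] = np.minimum(la, lb)
    return labels


def partition_aha17(mesh: HexMesh, septal_facets: np.ndarray) -> HexMesh:
    """Label every element with its AHA sector (1-17) from its centroid.

    The body is split into basal/mid/apical thirds along the long axis with
    6/6/4 circumferential sectors; the apex cap is sector 17.  The
    circumferential origin is the anterior RV insertion, taken as the
    counter-clockwise edge (viewed from the base, i.e. looking down -z) of the
    septal facet wedge; sector numbering advances across the septum so that
    sectors 2-3 (8-9, 14) are septal.  Centroids exactly on a boundary go to
    the lower-numbered sector.
    """
    if mesh.element_frame_r is None:
        raise RuntimeError("element frames missing; generate the mesh first")
    septal = np.asarray(septal_facets)
    if septal.size == 0:
        raise ValueError("septal facet set is empty; run septum detection first")
    # the insertion sits on the septal set's CCW *edge* (a facet node line):
    # anchoring sector boundaries on node lines keeps element centroids off
    # the boundaries, so sector populations stay balanced across densities
    quads = mesh.facet_sets["epi"][septal]
    pts = mesh.nodes[np.unique(quads.reshape(-1))]
    sep_az = np.degrees(np.arctan2(pts[:, 1], pts[:, 0])) % 360.0
    center, half = _circular_span(sep_az)
    theta0 = (center + half) % 360.0  # CCW edge of the septum = anterior insertion

    cen = mesh.element_centroids()
    az = np.degrees(np.arctan2(cen[:, 1], cen[:, 0])) % 360.0
    psi = (theta0 - az) % 360.0  # advances clockwise (from base) into the septum

    body = ~mesh.is_cap
    z = cen[:, 2]
    z_top, z_bot = 0.0, z[body].min()
    frac = (z_top - z) / (z_top - z_bot)  # 0 at base .. 1 at the cap rim

    eps = 1e-9
    sector = np.zeros(mesh.n_elements, dtype=int)
    basal = body & (frac <= 1.0 / 3.0 + eps)
    apical = body & (frac > 2.0 / 3.0 + eps)
    mid = body & ~basal & ~apical
    sector[basal] = _ring_sector(psi[basal], 6, 0.0, 0)
    sector[mid] = _ring_sector(psi[mid], 6, 0.0, 6)
    # apical ring: 4 sectors, the septal one (14) centered on the septum
    # center at psi = half; the offset snaps to the nearest node line so the
    # boundaries never bisect an element column
    offset = half - 45.0
    if mesh.density is not None:
        dpsi = 360.0 / mesh.density.n_circumferential
        offset = np.round(offset / dpsi) * dpsi
    sector[apical] = _ring_sector(psi[apical], 4, offset, 12)
    sector[mesh.is_cap] = 17

    mesh.element_sector = sector
    present = set(np.unique(sector))
    missing = sorted(set(range(1, 18)) - present)
    if missing:
        warnings.warn(f"mesh too coarse to populate AHA sectors {missing}", stacklevel=2)
    return mesh


# ---------------------------------------------------------------------------
# fibers
# ---------------------------------------------------------------------------

def assign_fibers(
    mesh: HexMesh, endo_angle: float = 60.0, epi_angle: float = -60.0
) -> HexMesh:
    """Rule-based myofiber field: helix angle linear in the transmural
    coordinate, ``endo_angle`` at the endocardium to ``epi_angle`` at the
    epicardium, fiber = cos(theta) e_c + sin(theta) e_l."""
    if mesh.element_frame_c is None:
        raise RuntimeError("element frames missing; generate the mesh first")
    t = (mesh.element_layer + 0.5) / mesh.n_transmural
    theta = np.radians(endo_angle + t * (epi_angle - endo_angle))
    fib = (
        np.cos(theta)[:, None] * mesh.element_frame_c
        + np.sin(theta)[:, None] * mesh.element_frame_l
    )
    mesh.fiber_vector = fib / np.linalg.norm(fib, axis=1, keepdims=True)
    mesh.extra["fiber_angles"] = (endo_angle, epi_angle)
    return mesh


def fiber_at(
    mesh: HexMesh, t: np.ndarray, element_ids: np.ndarray
) -> np.ndarray:
    """Fiber direction at arbitrary transmural coordinates t (per entry),
    using the stored helix-angle rule and each element's frame."""
    endo_angle, epi_angle = mesh.extra.get("fiber_angles", (60.0, -60.0))
    theta = np.radians(endo_angle + t * (epi_angle - endo_angle))
    fib = (
        np.cos(theta)[..., None] * mesh.element_frame_c[element_ids]
        + np.sin(theta)[..., None] * mesh.element_frame_l[element_ids]
    )
    return fib / np.linalg.norm(fib, axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# cavity volume
# ---------------------------------------------------------------------------

def cavity_volume(mesh: HexMesh, displacement: np.ndarray | None = None) -> float:
    """LV cavity volume (ml) of the (possibly deformed) endocardial surface.

    The endocardial facets are closed by a fan cap over the basal opening and
    the signed divergence-theorem volume of the resulting closed surface is
    evaluated.  Rigid motions leave the value unchanged exactly.
    """
    x = mesh.nodes if displacement is None else mesh.nodes + displacement
    quads = mesh.facet_sets["endo"]
    tris = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]], axis=0)
    # basal rim: endo nodes on the base plane of the *reference* mesh, ordered
    rim = np.unique(quads.reshape(-1))
    rim = rim[np.isclose(mesh.nodes[rim, 2], 0.0)]
    if len(rim) < 3:
        raise ValueError("endocardial surface has no basal rim to cap")
    order = np.argsort(np.arctan2(mesh.nodes[rim, 1], mesh.nodes[rim, 0]))
    rim = rim[order]
    cap_center = x[rim].mean(axis=0)
    # endo facet normals point into the cavity (out of the solid); for the
    # divergence theorem we need outward-from-cavity, hence the minus sign.
    p = x[tris]
    vol = -np.einsum("ki,ki->k", p[:, 0], np.cross(p[:, 1], p[:, 2])).sum() / 6.0
    a = x[rim]
    b = x[np.roll(rim, -1)]
    # cap triangles (center, a, b) oriented upward (+z = outward from cavity)
    vol += np.einsum("ki,ki->k", np.tile(cap_center, (len(rim), 1)),
                     np.cross(a, b)).sum() / 6.0
    vol_ml = vol / 1000.0
    if vol_ml <= 0:
        raise ValueError("non-positive cavity volume; check surface orientation")
    return float(vol_ml)
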