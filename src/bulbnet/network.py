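"""Stochastic construction of olfactory-bulb microcircuit networks.

A network instance is one seeded realization of a connectivity scheme:

* ``random``   — mitral cells randomly rotated; all pairings arise from
  chance overlap of lateral dendrites.
* ``directed`` — one mitral cell of each lateral glomerulus is rotated so a
  lateral dendrite passes near the soma of a central sister (alternating
  sisters); strengths stay at baseline.
* ``default``  — directed, plus 'super-inhibition': 100 extra shared
  granule cells proximal to the target sister, granule-|mitral x4 for the
  pair, and mitral->granule x3 distal (>100 um) on the directed dendrite.
* ``slice``    — default-style two-cell network (somata 50 um apart),
  granule cells farther than 100 um from the A-B plane discarded,
  dendrites randomly rotated.

Geometry is planar (granule-layer projection): the central glomerulus sits
at the origin, lateral glomeruli within an 850 x 850 um^2 field, 2 mitral
cells per glomerulus, 1000 PG cells per glomerulus, and a granule lattice
of 2500 cells per (100 um)^2 (2 um spacing).  Each mitral cell forms 10^4
reciprocal granule synapses (80 on the soma) whose granule cell is drawn
from the lattice sites within the granule dendritic extent (100 um in each
planar coordinate) of the synapse site; 100 reciprocal PG synapses; each PG
completes 25 mitral->PG synapses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cells import build_mitral, pg_variant_split, sample_leak_offsets
from .synapses import (
    DELAY_INH,
    SYNAPSE_TABLE,
    assign_delays,
    distance_decay,
    sample_lognormal_weights,
)

GRANULE_SPACING = 2.0  # um; 2500 granule cells per (100 um)^2
WINDOW_REACH = 100.0  # um; granule dendritic extent: a granule can form the
# reciprocal synapse if its soma lies within this distance of the synapse
# site in each planar coordinate (|dx|, |dy| <= 100 um)
FIELD = 850.0  # um; lateral glomeruli placed in this square around center
N_GM_SYNAPSES = 10_000  # reciprocal granule synapses per mitral
N_GM_SOMA = 80  # of which on the soma
N_PG_PER_GLOM = 1000
N_M2PG_RECIPROCAL = 100  # reciprocal mitral|->PG synapses per mitral
N_M2PG_PER_PG = 25  # each PG completes this many mitral->PG inputs
N_ORN2PG_PER_PG = 50
N_ORN2M_PER_MITRAL = 400
SUPER_EXTRA_GRANULES = 100
SUPER_GM_FACTOR = 4.0  # granule-|mitral strengthening for the pair
SUPER_MG_FACTOR = 3.0  # distal mitral->granule strengthening
PROXIMAL_PATH = 100.0  # um; proximal/distal boundary
SPINES_PER_GRANULE = 100

SCHEMES = ("random", "directed", "default", "slice")


@dataclass
class GranuleSynapses:
    """Columnar table of reciprocal mitral|->granule synapses."""

    mitral: np.ndarray  # presynaptic / host mitral index
    comp: np.ndarray  # mitral compartment index
    granule: np.ndarray  # granule cell index
    path: np.ndarray  # um, path distance of the site from the mitral soma
    dend: np.ndarray  # 0 soma, 1 primary, 2 secondary
    diam_ratio: np.ndarray
    x: np.ndarray
    y: np.ndarray
    w_inh: np.ndarray  # nS, granule-|mitral
    w_ampa: np.ndarray  # nS, mitral->granule AMPA
    w_nmda: np.ndarray  # nS, mitral->granule NMDA

    def __len__(self):
        return len(self.mitral)


@dataclass
class AggregateInfo:
    representative: np.ndarray  # granule index of each aggregate
    mitral: np.ndarray  # host mitral per aggregate
    syn_comp: np.ndarray  # (n_agg, 10) target compartments
    syn_w: np.ndarray  # (n_agg, 10) nS
    syn_delay: np.ndarray  # (n_agg, 10) ms (exponential stagger + 0.6)
    n_members: np.ndarray


@dataclass
class NetworkInstance:
    scheme: str
    seed: int
    n_lateral: int
    glom_pos: np.ndarray  # (n_glom, 2), central first
    mitral_soma: np.ndarray  # (n_mitral, 2)
    mitral_glom: np.ndarray  # (n_mitral,)
    mitral_rotation: np.ndarray  # (n_mitral,) radians
    granule_pos: np.ndarray  # (n_granule, 2)
    gm: GranuleSynapses
    pg_variant: np.ndarray  # (n_pg,) 0 plateauing, 1 LTS
    pg_glom: np.ndarray
    m2pg: dict  # columnar arrays: mitral, pg, delay
    pg2m: dict  # columnar arrays: pg, mitral, comp, w, delay
    super_edges: list = field(default_factory=list)  # (source B, target A)
    aggregates: Optional[AggregateInfo] = None
    granule_leak_offset: np.ndarray = field(default_factory=lambda: np.zeros(0))
    pg_leak_offset: np.ndarray = field(default_factory=lambda: np.zeros(0))
    meta: dict = field(default_factory=dict)

    @property
    def n_mitral(self):
        return len(self.mitral_soma)

    @property
    def n_granule(self):
        return len(self.granule_pos)

    def granule_degree(self) -> np.ndarray:
        """Number of distinct mitral cells each granule connects to."""
        pairs = np.unique(np.stack([self.gm.granule, self.gm.mitral], axis=1),
                          axis=0)
        deg = np.zeros(self.n_granule, dtype=int)
        np.add.at(deg, pairs[:, 0], 1)
        return deg

    def shared_granule_count(self) -> int:
        """Granule cells connected to two or more mitral cells."""
        return int(np.sum(self.granule_degree() >= 2))


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def _mitral_comp_geometry():
    """Static per-compartment geometry of the reduced mitral cell."""
    proto = build_mitral()
    meta = proto.meta
    lat = meta["lateral_comps"]  # (idx, lx, ly, path, diam)
    prim = meta["primary_comps"]  # (idx, path)
    return proto, lat, prim


_GEOM_CACHE = None


def _geom():
    global _GEOM_CACHE
    if _GEOM_CACHE is None:
        _GEOM_CACHE = _mitral_comp_geometry()
    return _GEOM_CACHE


def mitral_comp_positions(soma_xy, rotation, glom_xy):
    """Planar positions of every synapse-bearing mitral compartment.

    Returns (comp_idx, x, y, path, dend_type, diam_ratio) arrays.  Lateral
    compartments rotate with the cell; primary-dendrite compartments project
    onto the soma->glomerulus segment (the primary ascends to the tuft, so
    its granule-layer projection tracks that segment).
    """
    proto, lat, prim = _geom()
    c, s = math.cos(rotation), math.sin(rotation)
    lx, ly = lat[:, 1], lat[:, 2]
    rx = soma_xy[0] + c * lx - s * ly
    ry = soma_xy[1] + s * lx + c * ly
    lat_diam = lat[:, 4] / 3.4  # ratio to the proximal trunk diameter

    # primary compartments: spread along the planar soma->glomerulus segment
    seg = np.asarray(glom_xy) - np.asarray(soma_xy)
    plen = max(np.hypot(*seg), 1e-6)
    fr = np.array([p[1] for p in prim]) / 300.0  # path fraction along primary
    px = soma_xy[0] + seg[0] * fr * min(plen, 300.0) / plen
    py = soma_xy[1] + seg[1] * fr * min(plen, 300.0) / plen

    comp_idx = np.concatenate([[0], [p[0] for p in prim], lat[:, 0]]).astype(int)
    x = np.concatenate([[soma_xy[0]], px, rx])
    y = np.concatenate([[soma_xy[1]], py, ry])
    path = np.concatenate([[0.0], [p[1] for p in prim], lat[:, 3]])
    dend = np.concatenate([[0], np.ones(len(prim)), np.full(len(lat), 2)])
    diam = np.concatenate([[1.0], np.ones(len(prim)), lat_diam])
    length = np.concatenate([[0.0], np.full(len(prim), 75.0),
                             np.full(len(lat), 25.0)])
    # depth-band unit ids: lateral branches and trunks carry their own id
    # (from the morphology); the primary dendrite is one more unit; the soma
    # (-1) draws a band per synapse.
    prim_unit = int(lat[:, 5].max()) + 1 if len(lat) else 0
    branch = np.concatenate([[-1], np.full(len(prim), prim_unit),
                             lat[:, 5]]).astype(int)
    return comp_idx, x, y, path, dend, diam, length, branch


def build_network(scheme: str, n_lateral_glomeruli: int = 2,
                  seed: int = 0, separation: Optional[float] = None,
                  pg_per_glom: int = N_PG_PER_GLOM,
                  two_cell: bool = False) -> NetworkInstance:
    """Build one seeded network instance.

    ``separation`` places the first lateral mitral cell's soma at that
    distance from central sister A (used by slice / two-cell activity-
    dependent-inhibition networks).  ``two_cell`` keeps only mitral cells A
    (central) and B (first lateral), as in the paired in-vivo protocol.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; use one of {SCHEMES}")
    if not 0 <= n_lateral_glomeruli <= 6:
        raise ValueError("n_lateral_glomeruli must be in 0..6")
    if scheme == "slice":
        n_lateral_glomeruli = 1
        if separation is None:
            separation = 50.0
        if separation <= 0:
            raise ValueError("separation must be positive")

    rng = np.random.default_rng(seed)

    # -- glomeruli and mitral somata ------------------------------------
    glom = [np.zeros(2)]
    for _ in range(n_lateral_glomeruli):
        while True:
            p = rng.uniform(-FIELD / 2, FIELD / 2, size=2)
            if 150.0 < np.hypot(*p):  # distinct from the central glomerulus
                break
        glom.append(p)
    glom_pos = np.array(glom)

    soma, mgl = [], []
    for g, gp in enumerate(glom_pos):
        for _ in range(2):
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(150.0, 350.0)
            soma.append(gp + rad * np.array([math.cos(ang), math.sin(ang)]))
            mgl.append(g)
    mitral_soma = np.array(soma)
    mitral_glom = np.array(mgl)

    directed = scheme in ("directed", "default", "slice")
    super_inhib = scheme in ("default", "slice")

    # lateral mitral B at a fixed separation from central sister A
    if separation is not None and n_lateral_glomeruli >= 1:
        ang = rng.uniform(0, 2 * math.pi)
        mitral_soma[2] = mitral_soma[0] + separation * np.array(
            [math.cos(ang), math.sin(ang)])

    rotations = rng.uniform(0, 2 * math.pi, size=len(mitral_soma))
    super_edges = []
    if directed:
        for k in range(n_lateral_glomeruli):
            b = 2 + 2 * k  # first mitral of lateral glomerulus k
            a = k % 2  # alternate central sisters
            if scheme != "slice":
                # aim the straight branch of trunk 0 at the target soma
                d = mitral_soma[a] - mitral_soma[b]
                rotations[b] = math.atan2(d[1], d[0])
            if super_inhib:
                super_edges.append((b, a))

    if two_cell:
        keep = np.array([0, 2]) if n_lateral_glomeruli >= 1 else np.array([0])
        mitral_soma = mitral_soma[keep]
        mitral_glom = mitral_glom[keep]
        rotations = rotations[keep]
        super_edges = [(1, 0)] if super_inhib and len(keep) == 2 else []

    n_mitral = len(mitral_soma)

    # -- reciprocal granule synapses ------------------------------------
    all_m, all_comp, all_g, all_path, all_dend, all_diam = [], [], [], [], [], []
    all_x, all_y = [], []
    gid_map: dict[int, int] = {}
    g_pos: list[tuple[float, float]] = []

    def granule_of(ix: np.ndarray, iy: np.ndarray) -> np.ndarray:
        key = ix.astype(np.int64) * 1_000_003 + iy.astype(np.int64)
        out = np.empty(len(key), dtype=np.int64)
        for i, k in enumerate(key):
            gi = gid_map.get(k)
            if gi is None:
                gi = len(g_pos)
                gid_map[k] = gi
                g_pos.append((ix[i] * GRANULE_SPACING, iy[i] * GRANULE_SPACING))
            out[i] = gi
        return out

    half_cells = int(WINDOW_REACH / GRANULE_SPACING)  # 50 -> 100 per side

    for m in range(n_mitral):
        gxy = glom_pos[mitral_glom[m]]
        comp_idx, x, y, path, dend, diam, length, branch = \
            mitral_comp_positions(mitral_soma[m], rotations[m], gxy)
        # synapse counts: 80 on the soma, the rest uniform along the length
        weights = length.copy()
        weights[0] = 0.0
        counts = rng.multinomial(N_GM_SYNAPSES - N_GM_SOMA,
                                 weights / weights.sum())
        counts[0] = N_GM_SOMA
        rep = np.repeat(np.arange(len(comp_idx)), counts)
        sx, sy = x[rep], y[rep]
        ix0 = np.ceil((sx - WINDOW_REACH) / GRANULE_SPACING).astype(np.int64)
        iy0 = np.ceil((sy - WINDOW_REACH) / GRANULE_SPACING).astype(np.int64)
        ix = ix0 + rng.integers(0, 2 * half_cells, size=len(rep))
        iy = iy0 + rng.integers(0, 2 * half_cells, size=len(rep))
        gids = granule_of(ix, iy)
        all_m.append(np.full(len(rep), m))
        all_comp.append(comp_idx[rep])
        all_g.append(gids)
        all_path.append(path[rep])
        all_dend.append(dend[rep])
        all_diam.append(diam[rep])
        all_x.append(sx)
        all_y.append(sy)

    gm = GranuleSynapses(
        mitral=np.concatenate(all_m), comp=np.concatenate(all_comp),
        granule=np.concatenate(all_g), path=np.concatenate(all_path),
        dend=np.concatenate(all_dend), diam_ratio=np.concatenate(all_diam),
        x=np.concatenate(all_x), y=np.concatenate(all_y),
        w_inh=np.zeros(0), w_ampa=np.zeros(0), w_nmda=np.zeros(0))

    # -- super-inhibition: 100 extra shared granule cells ---------------
    if super_edges:
        deg_m = {}
        for (b, a) in super_edges:
            # singles of A on soma / primary / proximal secondary
            mask_a = gm.mitral == a
            deg = np.zeros(len(g_pos) + 1, dtype=int)
            pairs = np.unique(np.stack([gm.granule, gm.mitral], axis=1), axis=0)
            np.add.at(deg, pairs[:, 0], 1)
            prox = mask_a & (gm.path <= PROXIMAL_PATH) & \
                (deg[gm.granule] == 1)
            cand = np.unique(gm.granule[prox])
            if len(cand) > SUPER_EXTRA_GRANULES:
                cand = rng.choice(cand, SUPER_EXTRA_GRANULES, replace=False)
            # connect each to the closest compartment of B's directed dendrite
            comp_idx, bx, by, bpath, bdend, bdiam, _, _ = mitral_comp_positions(
                mitral_soma[b], rotations[b], glom_pos[mitral_glom[b]])
            lat_sel = bdend == 2
            gxy = np.array([g_pos[int(g)] for g in cand])
            d2 = ((gxy[:, None, 0] - bx[None, lat_sel]) ** 2
                  + (gxy[:, None, 1] - by[None, lat_sel]) ** 2)
            j = np.argmin(d2, axis=1)
            sel_idx = np.nonzero(lat_sel)[0][j]
            gm.mitral = np.concatenate([gm.mitral, np.full(len(cand), b)])
            gm.comp = np.concatenate([gm.comp, comp_idx[sel_idx]])
            gm.granule = np.concatenate([gm.granule, cand])
            gm.path = np.concatenate([gm.path, bpath[sel_idx]])
            gm.dend = np.concatenate([gm.dend, np.full(len(cand), 2.0)])
            gm.diam_ratio = np.concatenate([gm.diam_ratio, bdiam[sel_idx]])
            gm.x = np.concatenate([gm.x, bx[sel_idx]])
            gm.y = np.concatenate([gm.y, by[sel_idx]])
            deg_m[(b, a)] = len(cand)

    granule_pos = np.array(g_pos) if g_pos else np.zeros((0, 2))

    # -- weights ---------------------------------------------------------
    base_inh = (SYNAPSE_TABLE["granule_mitral"][0] if scheme in
                ("default", "slice") else
                SYNAPSE_TABLE["granule_mitral_baseline"][0])
    lam = np.where(gm.dend == 1, "primary", "secondary")
    decay = np.where(
        gm.dend == 0, 1.0,
        np.where(gm.dend == 1,
                 distance_decay(gm.path, "primary", 1.0),
                 distance_decay(gm.path, "secondary", 1.0) * gm.diam_ratio))
    w_inh = base_inh * decay
    w_ampa = np.full(len(gm), SYNAPSE_TABLE["mitral_granule_ampa"][0])

    if super_edges:
        shared = _shared_sets(gm)
        for (b, a) in super_edges:
            sh = shared.get((min(a, b), max(a, b)), set())
            if not sh:
                continue
            sh_arr = np.isin(gm.granule, np.fromiter(sh, dtype=np.int64))
            # granule-|mitral x4 onto the target A (pair-wide)
            w_inh[sh_arr & (gm.mitral == a)] *= SUPER_GM_FACTOR
            # mitral->granule x3 distal on B's dendrites onto shared granules
            w_ampa[sh_arr & (gm.mitral == b) &
                   (gm.path > PROXIMAL_PATH)] *= SUPER_MG_FACTOR
        # granule 'columns' around lateral mitral cells: x4 proximal
        lateral_ms = [b for (b, a) in super_edges]
        for b in lateral_ms:
            w_inh[(gm.mitral == b) & (gm.path <= PROXIMAL_PATH)] *= \
                SUPER_GM_FACTOR

    gm.w_inh = sample_lognormal_weights(w_inh, rng)
    gm.w_ampa = sample_lognormal_weights(w_ampa, rng)
    gm.w_nmda = gm.w_ampa * SYNAPSE_TABLE["mitral_granule_nmda"][0] / \
        SYNAPSE_TABLE["mitral_granule_ampa"][0]

    # -- slice pruning ----------------------------------------------------
    net_granule_keep = None
    if scheme == "slice" and n_mitral >= 3:
        a_xy, b_xy = mitral_soma[0], mitral_soma[2]
        d = b_xy - a_xy
        nvec = np.array([-d[1], d[0]]) / max(np.hypot(*d), 1e-9)
        dist = np.abs((granule_pos - a_xy) @ nvec)
        net_granule_keep = dist <= 100.0
        keep_syn = net_granule_keep[gm.granule]
        for name in ("mitral", "comp", "granule", "path", "dend", "diam_ratio",
                     "x", "y", "w_inh", "w_ampa", "w_nmda"):
            setattr(gm, name, getattr(gm, name)[keep_syn])
        # re-index granule ids compactly
        new_id = -np.ones(len(granule_pos), dtype=np.int64)
        new_id[net_granule_keep] = np.arange(net_granule_keep.sum())
        gm.granule = new_id[gm.granule]
        granule_pos = granule_pos[net_granule_keep]

    # -- PG cells ----------------------------------------------------------
    n_glom = len(glom_pos)
    n_pg = pg_per_glom * n_glom
    n_plat, n_lts = pg_variant_split(pg_per_glom)
    variant = np.tile(np.array([0] * n_plat + [1] * n_lts), n_glom)
    pg_glom = np.repeat(np.arange(n_glom), pg_per_glom)

    m2pg_m, m2pg_p = [], []
    pg2m_p, pg2m_m, pg2m_w = [], [], []
    for g in range(n_glom):
        ms = np.nonzero(mitral_glom == g)[0]
        pgs = np.arange(g * pg_per_glom, (g + 1) * pg_per_glom)
        if len(ms) == 0:
            continue
        scale = pg_per_glom / N_PG_PER_GLOM
        n_recip = max(int(round(N_M2PG_RECIPROCAL * scale)), 1)
        for m in ms:
            chosen = rng.choice(pgs, size=n_recip, replace=False)
            m2pg_m.append(np.full(n_recip, m))
            m2pg_p.append(chosen)
            pg2m_p.append(chosen)
            pg2m_m.append(np.full(n_recip, m))
            pg2m_w.append(np.full(n_recip, SYNAPSE_TABLE["pg_mitral"][0]))
        # complete 25 mitral->PG synapses per PG
        have = np.zeros(pg_per_glom, dtype=int)
        for arr in m2pg_p:
            sel = (arr >= pgs[0]) & (arr <= pgs[-1])
            np.add.at(have, arr[sel] - pgs[0], 1)
        need = np.maximum(N_M2PG_PER_PG - have, 0)
        extra_p = np.repeat(pgs, need)
        extra_m = rng.choice(ms, size=len(extra_p))
        m2pg_m.append(extra_m)
        m2pg_p.append(extra_p)

    m2pg = {
        "mitral": np.concatenate(m2pg_m) if m2pg_m else np.zeros(0, int),
        "pg": np.concatenate(m2pg_p) if m2pg_p else np.zeros(0, int),
    }
    m2pg["delay"] = assign_delays("mitral_to_pg", rng, size=len(m2pg["pg"]))
    pg2m = {
        "pg": np.concatenate(pg2m_p) if pg2m_p else np.zeros(0, int),
        "mitral": np.concatenate(pg2m_m) if pg2m_m else np.zeros(0, int),
        "w": sample_lognormal_weights(
            np.concatenate(pg2m_w), rng) if pg2m_w else np.zeros(0),
    }
    pg2m["delay"] = assign_delays("pg_to_mitral", rng, size=len(pg2m["pg"]))

    net = NetworkInstance(
        scheme=scheme, seed=seed, n_lateral=n_lateral_glomeruli,
        glom_pos=glom_pos, mitral_soma=mitral_soma, mitral_glom=mitral_glom,
        mitral_rotation=rotations, granule_pos=granule_pos, gm=gm,
        pg_variant=variant, pg_glom=pg_glom, m2pg=m2pg, pg2m=pg2m,
        super_edges=super_edges,
        granule_leak_offset=sample_leak_offsets("granule", len(granule_pos), rng),
        pg_leak_offset=sample_leak_offsets("pg", n_pg, rng),
        meta={"pg_per_glom": pg_per_glom},
    )
    return net


def _shared_sets(gm: GranuleSynapses) -> dict:
    """granules shared by each unordered mitral pair."""
    out: dict[tuple[int, int], set] = {}
    pairs = np.unique(np.stack([gm.granule, gm.mitral], axis=1), axis=0)
    by_g: dict[int, list[int]] = {}
    for g, m in pairs:
        by_g.setdefault(int(g), []).append(int(m))
    for g, ms in by_g.items():
        if len(ms) < 2:
            continue
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                key = (min(ms[i], ms[j]), max(ms[i], ms[j]))
                out.setdefault(key, set()).add(g)
    return out


# ---------------------------------------------------------------------------
# aggregation of non-shared granule cells
# ---------------------------------------------------------------------------


def aggregate_singles(net: NetworkInstance, ratio: int = 100,
                      rng: Optional[np.random.Generator] = None
                      ) -> NetworkInstance:
    """Aggregate singly-connected granule cells ``ratio``:1 per mitral cell.

    Shared granule cells are untouched.  Each aggregate keeps one
    mitral->granule input synapse (its representative's) and emits
    inhibition as 10 staggered synapses whose summed conductance integral
    equals the group total (i.e. ~10 x strength each for ratio 100),
    with exponentially distributed extra delays (SD 160 ms).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    rng = rng or np.random.default_rng(net.seed + 7_777)
    gm = net.gm
    deg = net.granule_degree()
    single = deg == 1

    reps, hosts, comps, ws, dels, sizes = [], [], [], [], [], []
    keep_syn = np.ones(len(gm), dtype=bool)
    n_syn_out = 10
    for m in range(net.n_mitral):
        sel = (gm.mitral == m) & single[gm.granule]
        gids = np.unique(gm.granule[sel])
        if len(gids) == 0:
            continue
        n_agg = max(int(round(len(gids) / ratio)), 1) if ratio > 1 else len(gids)
        if ratio == 1:
            # identity aggregation: bookkeeping only
            for g in gids:
                idx = np.nonzero(sel & (gm.granule == g))[0]
                reps.append(g)
                hosts.append(m)
                comps.append(np.full(n_syn_out, gm.comp[idx[0]]))
                w = np.zeros(n_syn_out)
                w[0] = gm.w_inh[idx].sum()
                ws.append(w)
                d = np.full(n_syn_out, DELAY_INH)
                dels.append(d)
                sizes.append(1)
            keep_syn[sel] = False
            continue
        perm = rng.permutation(gids)
        groups = np.array_split(perm, n_agg)
        # per-granule total inhibitory weight (a single granule may hold
        # several reciprocal synapses on the same mitral cell)
        idx_all = np.nonzero(sel)[0]
        g_of = gm.granule[idx_all]
        w_of = np.zeros(int(gids.max()) + 1)
        np.add.at(w_of, g_of, gm.w_inh[idx_all])
        order = np.argsort(g_of)
        idx_sorted = idx_all[order]
        g_sorted = g_of[order]
        for grp in groups:
            total_w = w_of[grp].sum()
            pos = np.searchsorted(g_sorted, np.sort(grp))
            syn_idx = idx_sorted[pos]  # one site per member granule
            rep_g = int(grp[0])
            pick = rng.choice(syn_idx, size=n_syn_out,
                              replace=len(syn_idx) < n_syn_out)
            reps.append(rep_g)
            hosts.append(m)
            comps.append(gm.comp[pick])
            ws.append(np.full(n_syn_out, total_w / n_syn_out))
            dels.append(DELAY_INH + rng.exponential(160.0, size=n_syn_out))
            sizes.append(len(grp))
        # drop all member synapses except the representative's input
        rep_set = np.array([int(g[0]) for g in groups])
        drop = sel & ~np.isin(gm.granule, rep_set)
        keep_syn[drop] = False

    agg = AggregateInfo(
        representative=np.array(reps, dtype=int),
        mitral=np.array(hosts, dtype=int),
        syn_comp=np.array(comps, dtype=int) if comps else np.zeros((0, n_syn_out), int),
        syn_w=np.array(ws) if ws else np.zeros((0, n_syn_out)),
        syn_delay=np.array(dels) if dels else np.zeros((0, n_syn_out)),
        n_members=np.array(sizes, dtype=int),
    )

    import copy
    out = copy.copy(net)
    out.gm = GranuleSynapses(
        **{name: getattr(gm, name)[keep_syn]
           for name in ("mitral", "comp", "granule", "path", "dend",
                        "diam_ratio", "x", "y", "w_inh", "w_ampa", "w_nmda")})
    if ratio > 1:
        # the representative keeps its excitatory input, but its inhibitory
        # output is superseded by the aggregate's 10 staggered synapses
        is_rep = np.isin(out.gm.granule, agg.representative)
        out.gm.w_inh = np.where(is_rep, 0.0, out.gm.w_inh)
    out.meta = dict(net.meta, aggregated=True, ratio=ratio)
    out.aggregates = agg
    return out


def aggregates_per_mitral(net: NetworkInstance) -> np.ndarray:
    """Number of aggregated singly-connected granule proxies per mitral."""
    if net.aggregates is None:
        raise ValueError("network has not been aggregated")
    counts = np.zeros(net.n_mitral, dtype=int)
    np.add.at(counts, net.aggregates.mitral, 1)
    return counts


def make_slice(net_or_seed, separation: float = 50.0, seed: int = 0
               ) -> NetworkInstance:
    """Two-cell slice network: central A + lateral B at ``separation`` um,
    granule cells farther than 100 um from the A-B plane discarded."""
    if separation <= 0:
        raise ValueError("separation must be positive")
    if isinstance(net_or_seed, NetworkInstance):
        seed = net_or_seed.seed
    return build_network("slice", 1, seed, separation=separation)


# ---------------------------------------------------------------------------
# connectivity report (anatomical arithmetic + measured statistics)
# ---------------------------------------------------------------------------

GLOMERULI_IN_REACH = 175
MT_PER_GLOMERULUS = 75
ACTIVE_LATERAL_MT = 2  # odor-activated lateral M/T cells that inhibit a cell
ACTIVE_GLOMERULI = 17  # odor-activated glomeruli within dendritic reach


def connectivity_report(net: Optional[NetworkInstance] = None,
                        proximal_contacts: int = 400,
                        spines_per_granule: int = SPINES_PER_GRANULE,
                        required_proximal: int = SUPER_EXTRA_GRANULES) -> dict:
    """Summary statistics and the super-inhibition connectivity arithmetic.

    The arithmetic chain uses the anatomical constants of the full-morphology
    bulb (~400 granule contacts proximal to a mitral soma, 100 spines per
    granule): disynaptic paths, the maximum number of super-inhibiting
    lateral M/T cells, the reachable M/T count, the upper-bound fraction,
    and the model-constrained fan-in.  When a network instance is supplied,
    its measured (reduced-morphology) counts are reported alongside.
    """
    report = {}
    paths = proximal_contacts * spines_per_granule
    max_super = paths // required_proximal
    reachable = GLOMERULI_IN_REACH * MT_PER_GLOMERULUS  # ~13,000
    sparsity_denominator = ACTIVE_GLOMERULI * MT_PER_GLOMERULUS // ACTIVE_LATERAL_MT
    report.update(
        proximal_contacts=proximal_contacts,
        spines_per_granule=spines_per_granule,
        disynaptic_paths=paths,
        max_super_inhibitors=max_super,
        reachable_mt=reachable,
        upper_bound_one_in=round(reachable / max_super),
        sparsity_denominator=sparsity_denominator,
        fan_in=round(13000 / sparsity_denominator),
    )
    if net is not None:
        gm = net.gm
        prox = np.zeros(net.n_mitral, dtype=int)
        sel = gm.path <= PROXIMAL_PATH
        np.add.at(prox, gm.mitral[sel], 1)
        report["measured_proximal_contacts_per_mitral"] = prox.tolist()
        report["measured_shared_granules"] = net.shared_granule_count()
        report["n_granule"] = net.n_granule
        report["n_mitral"] = net.n_mitral
    return report
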