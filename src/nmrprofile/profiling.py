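"""Targeted profiling by approximate MAP inference.

The observed spectrum is modelled as a linear mixture of library signatures
whose clusters may each shift within a bounded window. The squared-error loss
between spectrum and reconstruction maps to a Gibbs distribution over
(concentrations rho, shifts delta); because each cluster influences only a
small ppm interval, the loss factors over a partition of the axis into regions
with constant cluster-influence sets, giving a factor graph.

Inference is Rao-Blackwellized sequential Monte Carlo with iterative
narrowing: particles sample the shift vector from per-cluster truncated
Gaussian beliefs, concentrations are solved conditionally by nonnegative least
squares (the mixture is linear in rho), particles are scored by the Gibbs
log-probability, and the beliefs are refit to the elite sample and shrunk each
iteration until every belief is narrower than the axis spacing. The incumbent
best particle is retained across iterations, so the best loss never increases.

The NNLS solve is global (all compounds jointly) but performed through the
Gram matrix of the truncated signature columns, whose sparsity (clusters only
overlap nearby clusters) makes each particle evaluation cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import nnls as _scipy_nnls
from scipy.stats import truncnorm

from .model import (
    Cluster,
    CompoundSignature,
    InvalidParameterError,
    ProfileAssignment,
    SpectralLibrary,
    Spectrum,
    eval_lorentzian,
)

__all__ = [
    "INFLUENCE_EPS",
    "Region",
    "FactorGraph",
    "BeliefState",
    "InferenceConfig",
    "InferenceDiagnostics",
    "influence_interval",
    "partition_regions",
    "build_factor_graph",
    "region_loss",
    "gibbs_score",
    "fit_concentrations",
    "infer_map",
]

#: Amplitude fraction below which a Lorentzian no longer "influences" a point.
INFLUENCE_EPS = 1e-3


def influence_interval(cluster: Cluster, eps: float = INFLUENCE_EPS) -> tuple[float, float]:
    """The ppm interval outside which every peak of the cluster stays below
    ``eps`` of its apex for any in-window shift.

    A Lorentzian of half-width g falls to ``eps * h`` at distance
    ``g * sqrt(1/eps - 1)`` from its center; the cluster interval is the
    envelope over peaks, widened by the shift window.
    """
    reach = np.sqrt(1.0 / eps - 1.0)
    lo = min(p.center - p.fwhm / 2.0 * reach for p in cluster.peaks) + cluster.shift_lo
    hi = max(p.center + p.fwhm / 2.0 * reach for p in cluster.peaks) + cluster.shift_hi
    return float(lo), float(hi)


@dataclass(frozen=True)
class Region:
    """A half-open block [lo, hi) of the ppm axis on which the set of
    influencing clusters is constant."""

    lo: float
    hi: float
    cluster_ids: frozenset[str]


def partition_regions(
    lib: SpectralLibrary,
    axis: NDArray,
    exclusion: list[tuple[float, float]] | None = None,
    eps: float = INFLUENCE_EPS,
) -> list[Region]:
    """Partition the profiled axis into maximal blocks with constant
    cluster-influence sets.

    Boundaries are the influence-interval endpoints (clipped to the axis) plus
    any exclusion edges; blocks inside an exclusion interval are dropped, and
    blocks influenced by no cluster are retained with an empty label.
    """
    axis = np.asarray(axis, dtype=float)
    a_lo = float(axis[0])
    a_hi = float(axis[-1]) + float(axis[1] - axis[0])
    intervals = {cl.cluster_id: influence_interval(cl, eps) for _, cl in lib.clusters()}
    cuts = {a_lo, a_hi}
    for lo, hi in intervals.values():
        if hi > a_lo and lo < a_hi:
            cuts.add(max(lo, a_lo))
            cuts.add(min(hi, a_hi))
    excl = [tuple(e) for e in (exclusion or [])]
    for lo, hi in excl:
        if hi > a_lo and lo < a_hi:
            cuts.add(max(lo, a_lo))
            cuts.add(min(hi, a_hi))
    bounds = sorted(cuts)
    regions = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (lo + hi)
        if any(e_lo <= mid < e_hi for e_lo, e_hi in excl):
            continue
        label = frozenset(
            cid for cid, (i_lo, i_hi) in intervals.items() if i_lo <= mid < i_hi
        )
        regions.append(Region(lo, hi, label))
    return regions


@dataclass
class FactorGraph:
    """Bipartite structure: one factor per non-empty region, linked to the
    shift variables of its clusters and the concentration variables of their
    parent compounds."""

    concentration_vars: list[str]
    shift_vars: list[str]
    factors: list[tuple[Region, frozenset[str], frozenset[str]]]  # (region, shift vars, conc vars)

    def reachable_variables(self) -> set[str]:
        out: set[str] = set()
        for _, svars, cvars in self.factors:
            out |= svars | cvars
        return out


def build_factor_graph(
    lib: SpectralLibrary,
    axis: NDArray,
    exclusion: list[tuple[float, float]] | None = None,
    eps: float = INFLUENCE_EPS,
) -> FactorGraph:
    regions = partition_regions(lib, axis, exclusion, eps)
    owner = {cl.cluster_id: comp.name for comp, cl in lib.clusters()}
    factors = []
    for r in regions:
        if not r.cluster_ids:
            continue
        factors.append((r, r.cluster_ids, frozenset(owner[c] for c in r.cluster_ids)))
    return FactorGraph(
        concentration_vars=lib.names,
        shift_vars=list(owner.keys()),
        factors=factors,
    )


# ---------------------------------------------------------------------------
# Loss and score
# ---------------------------------------------------------------------------

def region_loss(
    region: Region,
    spectrum: Spectrum,
    lib: SpectralLibrary,
    assign: ProfileAssignment,
) -> float:
    """Sum of squared residuals over the region's grid points, with the
    reconstruction restricted to the region's clusters."""
    x = spectrum.ppm_axis
    sel = (x >= region.lo) & (x < region.hi)
    if not sel.any():
        return 0.0
    xs = x[sel]
    recon = np.zeros_like(xs)
    for comp, cl in lib.clusters():
        if cl.cluster_id not in region.cluster_ids:
            continue
        rho = assign.concentrations.get(comp.name, 0.0)
        if rho == 0.0:
            continue
        d = assign.shifts.get(cl.cluster_id, 0.0)
        for pk in cl.peaks:
            recon += rho * eval_lorentzian(pk, d, xs)
    res = spectrum.real[sel] - recon
    return float(res @ res)


def gibbs_score(total_loss: float, noise_sigma: float) -> float:
    """Gibbs log-probability (up to the log-partition constant):
    ``-loss / (2 sigma^2)``. Lower loss -> higher score."""
    if noise_sigma <= 0:
        raise InvalidParameterError("noise_sigma must be > 0")
    return -total_loss / (2.0 * noise_sigma**2)


# ---------------------------------------------------------------------------
# Conditional concentration solve
# ---------------------------------------------------------------------------

def _signature_column(
    comp: CompoundSignature, shifts: dict[str, float], axis: NDArray
) -> NDArray:
    col = np.zeros_like(axis)
    for cl in comp.clusters:
        d = shifts.get(cl.cluster_id, 0.0)
        for pk in cl.peaks:
            col += eval_lorentzian(pk, d, axis)
    return col


def fit_concentrations(
    spectrum: Spectrum,
    lib: SpectralLibrary,
    shifts: dict[str, float],
    profiled_mask: NDArray | None = None,
) -> dict[str, float]:
    """Solve nonnegative least squares for all concentrations at fixed shifts.

    Design columns are unit-concentration compound signatures evaluated on the
    full (optionally masked) axis. Exact duplicate signatures are reported
    with an ambiguity warning; the solver's least-norm behavior breaks ties.
    """
    if len(lib) == 0:
        return {}
    axis = spectrum.ppm_axis
    cols = np.column_stack([_signature_column(c, shifts, axis) for c in lib.compounds])
    y = spectrum.real
    if profiled_mask is not None:
        cols = cols[profiled_mask]
        y = y[profiled_mask]
    keys = [
        tuple((cl.shift_lo, cl.shift_hi) + tuple((p.height, p.center, p.fwhm) for p in cl.peaks)
              for cl in c.clusters)
        for c in lib.compounds
    ]
    seen: dict = {}
    for name, key in zip(lib.names, keys):
        if key in seen:
            warnings.warn(
                f"duplicate compound signatures: {seen[key]!r} and {name!r} "
                "are indistinguishable; concentrations split arbitrarily"
            )
        seen[key] = name
    rho, _ = _scipy_nnls(cols, y)
    return dict(zip(lib.names, rho.astype(float)))


def _gram_nnls(g: NDArray, b: NDArray) -> NDArray:
    """NNLS through the Gram matrix: minimize rho' G rho - 2 b' rho, rho >= 0,
    via Cholesky factorization and the compiled Lawson-Hanson solver."""
    m = g.shape[0]
    ridge = 1e-10 * max(float(np.trace(g)) / m, 1e-300)
    c, low = cho_factor(g + ridge * np.eye(m), lower=True)
    l = np.tril(c) if low else np.triu(c).T
    rhs = solve_triangular(l, b, lower=True)
    rho, _ = _scipy_nnls(l.T, rhs)
    return rho


# ---------------------------------------------------------------------------
# Iterative-narrowing sequential Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class BeliefState:
    """Truncated-Gaussian proposal for one shift variable."""

    cluster_id: str
    lo: float
    hi: float
    mean: float
    std: float
    frozen: bool = False


@dataclass
class InferenceConfig:
    n_particles: int = 256
    elite_fraction: float = 0.25
    shrink: float = 0.9
    max_iter: int = 30
    seed: int = 0
    exclusion: list[tuple[float, float]] = field(default_factory=lambda: [(4.6, 5.0)])
    eps: float = INFLUENCE_EPS
    rho_max_factor: float = 2.0
    #: a narrowed cluster whose region residual RMS still exceeds this many
    #: noise sigmas is considered misassigned and its belief is re-widened
    rewiden_rms: float = 3.0
    max_rewiden: int = 3


@dataclass
class InferenceDiagnostics:
    converged: bool
    iterations: int
    final_loss: float
    loss_trace: list[float]
    belief_trace: list[dict[str, tuple[float, float]]]
    rho_stats: dict[str, tuple[float, float]]


@dataclass
class _ClusterInfo:
    cluster: Cluster
    comp_index: int
    sl: slice
    heights: NDArray
    centers: NDArray
    gammas: NDArray
    mask: NDArray  # profiled-point mask restricted to the slice


def _eval_cluster(info: _ClusterInfo, x: NDArray, deltas: NDArray) -> NDArray:
    """(K, L) matrix of the cluster's peak-sum at each particle shift."""
    dx = x[None, :] - deltas[:, None]
    out = np.zeros_like(dx)
    for h, c, g in zip(info.heights, info.centers, info.gammas):
        d = dx - c
        out += h * g * g / (d * d + g * g)
    out *= info.mask[None, :]
    return out


def infer_map(
    spectrum: Spectrum,
    lib: SpectralLibrary,
    config: InferenceConfig | None = None,
) -> tuple[ProfileAssignment, InferenceDiagnostics]:
    """Approximate-MAP profile of a processed, referenced real spectrum.

    Returns the best particle's shifts with their conditionally fitted
    nonnegative concentrations, plus per-iteration diagnostics (belief means
    and stds, best-loss trace).
    """
    cfg = config or InferenceConfig()
    if len(lib) == 0:
        diag = InferenceDiagnostics(True, 0, 0.0, [], [], {})
        return ProfileAssignment({}, {}), diag
    if abs(lib.frequency - spectrum.frequency) > 1e-6 * lib.frequency:
        raise InvalidParameterError(
            f"library frequency {lib.frequency} MHz does not match spectrum "
            f"frequency {spectrum.frequency} MHz"
        )
    sigma = spectrum.noise_sigma
    if sigma is None or sigma <= 0:
        from .processing import estimate_noise

        sigma = estimate_noise(spectrum)
        sigma = max(sigma, 1e-12 * max(1.0, float(np.abs(spectrum.real).max())))

    axis = spectrum.ppm_axis
    n = axis.size
    spacing = spectrum.spacing
    profiled = np.ones(n, dtype=bool)
    for lo, hi in cfg.exclusion:
        profiled &= ~((axis >= lo) & (axis < hi))
    y = spectrum.real * profiled

    comp_names = lib.names
    m = len(comp_names)
    infos: list[_ClusterInfo] = []
    beliefs: list[BeliefState] = []
    for ci, comp in enumerate(lib.compounds):
        for cl in comp.clusters:
            i_lo, i_hi = influence_interval(cl, cfg.eps)
            a = int(np.clip(np.searchsorted(axis, i_lo, "left"), 0, n))
            b_ = int(np.clip(np.searchsorted(axis, i_hi, "left"), 0, n))
            sl = slice(a, b_)
            infos.append(
                _ClusterInfo(
                    cl,
                    ci,
                    sl,
                    np.array([p.height for p in cl.peaks]),
                    np.array([p.center for p in cl.peaks]),
                    np.array([p.fwhm / 2.0 for p in cl.peaks]),
                    profiled[sl].astype(float),
                )
            )
            width = cl.shift_hi - cl.shift_lo
            beliefs.append(
                BeliefState(
                    cl.cluster_id,
                    cl.shift_lo,
                    cl.shift_hi,
                    0.5 * (cl.shift_lo + cl.shift_hi),
                    width / 2.0,
                    frozen=width / 2.0 < spacing,
                )
            )
    nc = len(infos)

    # static sparsity: which cluster pairs can overlap on the axis
    pairs: list[tuple[int, int]] = []
    overlapping: list[list[int]] = [[] for _ in range(nc)]
    for i in range(nc):
        for j in range(i, nc):
            a = max(infos[i].sl.start, infos[j].sl.start)
            b_ = min(infos[i].sl.stop, infos[j].sl.stop)
            if b_ > a:
                pairs.append((i, j))
                overlapping[i].append(j)
                if i != j:
                    overlapping[j].append(i)

    rho_max = np.full(m, np.inf)
    ymax = float(np.abs(y).max()) if n else 0.0
    for ci, comp in enumerate(lib.compounds):
        peak_h = comp.max_unit_intensity()
        if peak_h > 0:
            rho_max[ci] = cfg.rho_max_factor * ymax / peak_h

    const = float(y @ y)
    k_part = cfg.n_particles
    n_elite = max(1, int(round(cfg.elite_fraction * k_part)))
    rng = np.random.default_rng(cfg.seed)
    std_floor = 0.05 * spacing

    best_loss = np.inf
    best_delta = np.array([b.mean for b in beliefs])
    best_rho = np.zeros(m)
    loss_trace: list[float] = []
    belief_trace: list[dict[str, tuple[float, float]]] = []
    rho_stats: dict[str, tuple[float, float]] = {}
    it = 0
    converged = False
    cache: dict[int, NDArray] = {}  # frozen-cluster single-row evaluations

    rewidened = np.zeros(nc, dtype=int)
    for it in range(1, cfg.max_iter + 1):
        deltas = np.empty((k_part, nc))
        for c in range(nc):
            b = beliefs[c]
            if b.frozen:
                deltas[:, c] = b.mean
            else:
                a_ = (b.lo - b.mean) / b.std
                b2 = (b.hi - b.mean) / b.std
                deltas[:, c] = truncnorm.rvs(
                    a_, b2, loc=b.mean, scale=b.std, size=k_part, random_state=rng
                )
        if np.isfinite(best_loss):
            # incumbent elitism on the free dimensions
            for c in range(nc):
                if not beliefs[c].frozen:
                    deltas[0, c] = best_delta[c]

        # per-cluster particle evaluations
        vmats: list[NDArray] = []
        for c, info in enumerate(infos):
            x = axis[info.sl]
            if beliefs[c].frozen:
                if c not in cache:
                    cache[c] = _eval_cluster(info, x, np.array([beliefs[c].mean]))
                vmats.append(cache[c])
            else:
                vmats.append(_eval_cluster(info, x, deltas[:, c]))

        # b vector per particle: (K, M)
        bmat = np.zeros((k_part, m))
        for c, info in enumerate(infos):
            contrib = vmats[c] @ y[info.sl]
            bmat[:, info.comp_index] += contrib if contrib.size > 1 else contrib[0]

        # Gram tensor per particle, assembled from overlapping cluster pairs
        gmat = np.zeros((k_part, m, m))
        for i, j in pairs:
            a = max(infos[i].sl.start, infos[j].sl.start)
            b_ = min(infos[i].sl.stop, infos[j].sl.stop)
            vi = vmats[i][:, a - infos[i].sl.start : b_ - infos[i].sl.start]
            vj = vmats[j][:, a - infos[j].sl.start : b_ - infos[j].sl.start]
            if vi.shape[0] == 1 and vj.shape[0] == 1:
                dots = np.full(k_part, float(vi[0] @ vj[0]))
            else:
                if vi.shape[0] == 1:
                    vi = np.broadcast_to(vi, vj.shape)
                if vj.shape[0] == 1:
                    vj = np.broadcast_to(vj, vi.shape)
                dots = np.einsum("kl,kl->k", vi, vj)
            mi, mj = infos[i].comp_index, infos[j].comp_index
            gmat[:, mi, mj] += dots
            if (mi, mj) != (mj, mi):
                pass
            if mi != mj:
                gmat[:, mj, mi] += dots
            elif i != j:
                gmat[:, mi, mj] += dots  # symmetric intra-compound cross term

        losses = np.empty(k_part)
        rhos = np.empty((k_part, m))
        for k in range(k_part):
            rho = _gram_nnls(gmat[k], bmat[k])
            np.minimum(rho, rho_max, out=rho)
            rhos[k] = rho
            losses[k] = const - 2.0 * (bmat[k] @ rho) + rho @ gmat[k] @ rho

        order = np.argsort(losses, kind="stable")
        if losses[order[0]] < best_loss:
            best_loss = float(losses[order[0]])
            best_delta = deltas[order[0]].copy()
            best_rho = rhos[order[0]].copy()
        loss_trace.append(best_loss)

        # per-cluster elite selection on the LOCAL loss (the factor graph's
        # decomposition): a cluster's belief is refit from the particles that
        # reconstruct its own influence region best, which keeps the per-
        # dimension selection pressure independent of the problem size
        elite_idx = order[:n_elite]
        for c in range(nc):
            b = beliefs[c]
            info = infos[c]
            a0, b0 = info.sl.start, info.sl.stop
            if b0 <= a0:
                if not b.frozen:
                    e = deltas[elite_idx, c]
                    b.mean = float(np.clip(e.mean(), b.lo, b.hi))
                    b.std = float(max(cfg.shrink * e.std(), std_floor))
                    b.frozen = b.std < spacing
                continue
            recon = np.zeros((k_part, b0 - a0))
            for c2 in overlapping[c]:
                o_lo = max(a0, infos[c2].sl.start)
                o_hi = min(b0, infos[c2].sl.stop)
                v2 = vmats[c2][:, o_lo - infos[c2].sl.start : o_hi - infos[c2].sl.start]
                contrib = rhos[:, infos[c2].comp_index : infos[c2].comp_index + 1] * v2
                recon[:, o_lo - a0 : o_hi - a0] += contrib
            res = y[a0:b0][None, :] - recon
            local_loss = np.einsum("kl,kl->k", res, res)
            local_order = np.argsort(local_loss, kind="stable")
            # re-widening guard: a narrowed belief whose region still holds
            # unexplained residual has locked onto the wrong explanation;
            # restart its search over the full window
            narrow = b.frozen or b.std < 2 * spacing
            # unexplained-residual floor: noise, or the reconstruction's own
            # tail-truncation error, whichever dominates
            local_ymax = float(np.abs(y[a0:b0]).max()) if b0 > a0 else 0.0
            floor_loss = (b0 - a0) * max(
                (cfg.rewiden_rms * sigma) ** 2, (3.0 * cfg.eps * local_ymax) ** 2
            )
            if (
                narrow
                and b.hi > b.lo
                and local_loss[local_order[0]] > floor_loss
                and rewidened[c] < cfg.max_rewiden
                and it < cfg.max_iter - 5
            ):
                rewidened[c] += 1
                b.frozen = False
                b.mean = 0.5 * (b.lo + b.hi)
                b.std = max((b.hi - b.lo) / 2.0, std_floor)
                cache.pop(c, None)
                continue
            if b.frozen:
                continue
            e = deltas[local_order[:n_elite], c]
            b.mean = float(np.clip(e.mean(), b.lo, b.hi))
            b.std = float(max(cfg.shrink * e.std(), std_floor))
            if b.std < spacing:
                b.frozen = True
                cache.pop(c, None)
        belief_trace.append({b.cluster_id: (b.mean, b.std) for b in beliefs})
        rho_stats = {
            name: (float(rhos[elite_idx, i].mean()), float(rhos[elite_idx, i].std()))
            for i, name in enumerate(comp_names)
        }
        if all(b.frozen for b in beliefs):
            converged = True
            break

    # final assignment: the mode of the narrowed beliefs, with concentrations
    # re-solved at the mode shifts, then a deterministic per-cluster scan of
    # each shift window conditioned on the others. The scan rescues weak
    # clusters whose belief locked onto a stronger coincident neighbor (the
    # narrowing can stay in the wrong basin when a 10x taller signature
    # explains most of the region) and snaps borderline shifts to the
    # conditional optimum.
    def solve_at(delta: NDArray) -> tuple[NDArray, float, list[NDArray], NDArray, NDArray]:
        bvec = np.zeros(m)
        cols = []
        for c, info in enumerate(infos):
            v = _eval_cluster(info, axis[info.sl], delta[c : c + 1])[0]
            cols.append(v)
            bvec[info.comp_index] += float(v @ y[info.sl])
        g = np.zeros((m, m))
        for i, j in pairs:
            a = max(infos[i].sl.start, infos[j].sl.start)
            b_ = min(infos[i].sl.stop, infos[j].sl.stop)
            vi = cols[i][a - infos[i].sl.start : b_ - infos[i].sl.start]
            vj = cols[j][a - infos[j].sl.start : b_ - infos[j].sl.start]
            dot = float(vi @ vj)
            mi, mj = infos[i].comp_index, infos[j].comp_index
            g[mi, mj] += dot
            if mi != mj:
                g[mj, mi] += dot
            elif i != j:
                g[mi, mj] += dot
        rho = np.minimum(_gram_nnls(g, bvec), rho_max)
        loss = const - 2.0 * (bvec @ rho) + rho @ g @ rho
        return rho, float(loss), cols, bvec, g

    mode_delta = np.array([b.mean for b in beliefs])
    mode_rho, mode_loss, cols, bvec, g = solve_at(mode_delta)
    if mode_loss > best_loss:
        mode_delta = best_delta.copy()
        mode_rho, mode_loss, cols, bvec, g = solve_at(mode_delta)

    def eval_candidate(c: int, dv: float):
        """Loss/state if cluster c moved to dv, via incremental Gram update."""
        info = infos[c]
        x = axis[info.sl]
        mi = info.comp_index
        v_old = cols[c]
        v_new = _eval_cluster(info, x, np.array([dv]))[0]
        bvec2 = bvec.copy()
        bvec2[mi] += float((v_new - v_old) @ y[info.sl])
        g2 = g.copy()
        for c2 in overlapping[c]:
            a = max(info.sl.start, infos[c2].sl.start)
            b_ = min(info.sl.stop, infos[c2].sl.stop)
            s_self = slice(a - info.sl.start, b_ - info.sl.start)
            mj = infos[c2].comp_index
            if c2 == c:
                g2[mi, mi] += float(v_new @ v_new) - float(v_old @ v_old)
            else:
                v2 = cols[c2][a - infos[c2].sl.start : b_ - infos[c2].sl.start]
                d_dot = float(v_new[s_self] @ v2) - float(v_old[s_self] @ v2)
                g2[mi, mj] += d_dot
                if mi != mj:
                    g2[mj, mi] += d_dot
                else:
                    g2[mi, mj] += d_dot
        rho2 = np.minimum(_gram_nnls(g2, bvec2), rho_max)
        loss2 = float(const - 2.0 * (bvec2 @ rho2) + rho2 @ g2 @ rho2)
        return loss2, rho2, bvec2, g2, v_new

    n_scan = 33
    tol = 1e-12 * max(const, 1.0)

    def single_sweeps(max_sweeps: int) -> None:
        nonlocal mode_loss, mode_rho, bvec, g
        for _sweep in range(max_sweeps):
            improved = False
            for c in range(nc):
                cl = infos[c].cluster
                if cl.shift_hi - cl.shift_lo <= 0 or infos[c].sl.stop <= infos[c].sl.start:
                    continue
                # coarse scan of the window, then bisection refinement
                best_c = (mode_loss, None)
                for dv in np.linspace(cl.shift_lo, cl.shift_hi, n_scan):
                    loss2, rho2, bvec2, g2, v_new = eval_candidate(c, float(dv))
                    if loss2 < best_c[0] - tol:
                        best_c = (loss2, (float(dv), rho2, bvec2, g2, v_new))
                if best_c[1] is not None:
                    dv, mode_rho, bvec, g, cols[c] = best_c[1]
                    mode_delta[c] = dv
                    mode_loss = best_c[0]
                    improved = True
                step = (cl.shift_hi - cl.shift_lo) / (n_scan - 1)
                while step > 0.03 * spacing:
                    step /= 2.0
                    for dv in (mode_delta[c] - step, mode_delta[c] + step):
                        if not (cl.shift_lo <= dv <= cl.shift_hi):
                            continue
                        loss2, rho2, bvec2, g2, v_new = eval_candidate(c, float(dv))
                        if loss2 < mode_loss - tol:
                            mode_delta[c] = float(dv)
                            mode_rho, bvec, g, cols[c] = rho2, bvec2, g2, v_new
                            mode_loss = loss2
                            improved = True
                            break
            if not improved:
                break

    single_sweeps(2)

    # pair rescue: two coincident clusters can swap identities, a state no
    # single-coordinate move escapes. For overlapping pairs whose regions
    # still hold residual above the noise/truncation floor, scan both windows
    # jointly and keep the best joint assignment.
    def region_residual(c: int) -> tuple[float, float]:
        info = infos[c]
        a0, b0 = info.sl.start, info.sl.stop
        if b0 <= a0:
            return 0.0, np.inf
        recon = np.zeros(b0 - a0)
        for c2 in overlapping[c]:
            o_lo = max(a0, infos[c2].sl.start)
            o_hi = min(b0, infos[c2].sl.stop)
            v2 = cols[c2][o_lo - infos[c2].sl.start : o_hi - infos[c2].sl.start]
            recon[o_lo - a0 : o_hi - a0] += mode_rho[infos[c2].comp_index] * v2
        res = y[a0:b0] - recon
        local_ymax = float(np.abs(y[a0:b0]).max())
        floor = (b0 - a0) * max(
            (cfg.rewiden_rms * sigma) ** 2, (3.0 * cfg.eps * local_ymax) ** 2
        )
        return float(res @ res), floor

    def pair_rescue() -> bool:
        nonlocal mode_delta, mode_loss, mode_rho, bvec, g, cols
        resid_excess = {}
        for c in range(nc):
            r, floor = region_residual(c)
            if r > floor:
                resid_excess[c] = r - floor
        sus_pairs = [
            (i, j)
            for i, j in pairs
            if i != j and (i in resid_excess or j in resid_excess)
            and infos[i].cluster.shift_hi > infos[i].cluster.shift_lo
            and infos[j].cluster.shift_hi > infos[j].cluster.shift_lo
        ]
        sus_pairs.sort(
            key=lambda p: resid_excess.get(p[0], 0.0) + resid_excess.get(p[1], 0.0),
            reverse=True,
        )
        sus_pairs = sus_pairs[:24]
        n_pair = 17
        moved_any = False
        for i, j in sus_pairs:
            cl_i, cl_j = infos[i].cluster, infos[j].cluster
            saved = (mode_delta.copy(), mode_rho, mode_loss, list(cols), bvec, g)
            best_pair = (mode_loss, None)
            for dv1 in np.linspace(cl_i.shift_lo, cl_i.shift_hi, n_pair):
                l1, r1, b1, g1, v1 = eval_candidate(i, float(dv1))
                # commit i -> dv1 provisionally
                cols[i], bvec, g, mode_rho = v1, b1, g1, r1
                mode_delta[i] = float(dv1)
                for dv2 in np.linspace(cl_j.shift_lo, cl_j.shift_hi, n_pair):
                    l2, *_rest = eval_candidate(j, float(dv2))
                    if l2 < best_pair[0] - tol:
                        best_pair = (l2, (float(dv1), float(dv2)))
                # restore state for next dv1
                mode_delta, mode_rho, mode_loss, cols, bvec, g = (
                    saved[0].copy(), saved[1], saved[2], list(saved[3]), saved[4], saved[5]
                )
            if best_pair[1] is not None:
                dv1, dv2 = best_pair[1]
                _, r1, b1, g1, v1 = eval_candidate(i, dv1)
                cols[i], bvec, g, mode_rho = v1, b1, g1, r1
                mode_delta[i] = dv1
                l2, r2, b2, g2, v2 = eval_candidate(j, dv2)
                cols[j], bvec, g, mode_rho = v2, b2, g2, r2
                mode_delta[j] = dv2
                mode_loss = l2
                moved_any = True
                # local bisection refinement of the two moved clusters
                for c in (i, j):
                    cl = infos[c].cluster
                    step = (cl.shift_hi - cl.shift_lo) / (n_pair - 1)
                    while step > 0.03 * spacing:
                        step /= 2.0
                        for dv in (mode_delta[c] - step, mode_delta[c] + step):
                            if not (cl.shift_lo <= dv <= cl.shift_hi):
                                continue
                            loss2, rho2, bvec2, g2, v_new = eval_candidate(c, float(dv))
                            if loss2 < mode_loss - tol:
                                mode_delta[c] = float(dv)
                                mode_rho, bvec, g, cols[c] = rho2, bvec2, g2, v_new
                                mode_loss = loss2
                                break
        return moved_any

    def triple_rescue() -> bool:
        """3-D window scan for mutually-overlapping suspicious clusters:
        three coincident clusters can be cyclically misassigned, which no
        single or pairwise move escapes."""
        nonlocal mode_delta, mode_loss, mode_rho, bvec, g, cols
        resid_excess = {}
        for c in range(nc):
            r, floor = region_residual(c)
            if r > floor:
                resid_excess[c] = r - floor
        overlap_sets = {c: set(overlapping[c]) for c in resid_excess}
        triples = []
        sus = sorted(resid_excess, key=resid_excess.get, reverse=True)
        for a_i in sus:
            for b_i in overlap_sets[a_i]:
                for c_i in overlap_sets[a_i]:
                    if not (a_i < b_i < c_i):
                        continue
                    if b_i in overlap_sets and c_i in overlap_sets.get(b_i, set()):
                        pass
                    if c_i not in set(overlapping[b_i]):
                        continue
                    if all(
                        infos[x].cluster.shift_hi > infos[x].cluster.shift_lo
                        for x in (a_i, b_i, c_i)
                    ):
                        triples.append((a_i, b_i, c_i))
        triples = triples[:4]
        n_grid = 13
        moved_any = False
        for tri in triples:
            saved = (mode_delta.copy(), mode_rho, mode_loss, list(cols), bvec, g)
            best_t = (mode_loss, None)
            cl0, cl1, cl2 = (infos[x].cluster for x in tri)
            for dv0 in np.linspace(cl0.shift_lo, cl0.shift_hi, n_grid):
                _, r0, b0_, g0_, v0 = eval_candidate(tri[0], float(dv0))
                cols[tri[0]], bvec, g, mode_rho = v0, b0_, g0_, r0
                mode_delta[tri[0]] = float(dv0)
                inner = (mode_delta.copy(), mode_rho, list(cols), bvec, g)
                for dv1 in np.linspace(cl1.shift_lo, cl1.shift_hi, n_grid):
                    _, r1, b1_, g1_, v1 = eval_candidate(tri[1], float(dv1))
                    cols[tri[1]], bvec, g, mode_rho = v1, b1_, g1_, r1
                    mode_delta[tri[1]] = float(dv1)
                    for dv2 in np.linspace(cl2.shift_lo, cl2.shift_hi, n_grid):
                        l2, *_rest = eval_candidate(tri[2], float(dv2))
                        if l2 < best_t[0] - tol:
                            best_t = (l2, (float(dv0), float(dv1), float(dv2)))
                    mode_delta, mode_rho, cols, bvec, g = (
                        inner[0].copy(), inner[1], list(inner[2]), inner[3], inner[4]
                    )
                mode_delta, mode_rho, mode_loss, cols, bvec, g = (
                    saved[0].copy(), saved[1], saved[2], list(saved[3]), saved[4], saved[5]
                )
            if best_t[1] is not None:
                for x, dv in zip(tri, best_t[1]):
                    _, rx, bx, gx, vx = eval_candidate(x, dv)
                    cols[x], bvec, g, mode_rho = vx, bx, gx, rx
                    mode_delta[x] = dv
                    mode_loss = float(
                        const - 2.0 * (bvec @ mode_rho) + mode_rho @ g @ mode_rho
                    )
                moved_any = True
        return moved_any

    for _round in range(4):
        if not pair_rescue():
            break
        single_sweeps(1)
    if triple_rescue():
        single_sweeps(1)
        if pair_rescue():
            single_sweeps(1)

    final_delta, final_rho = mode_delta, mode_rho
    final_loss = float(min(mode_loss, best_loss))

    # final exact solve: the in-loop Gram uses tail-truncated columns (the
    # influence-interval cutoff), whose unmodelled tail mass absent compounds
    # would otherwise soak up as small spurious concentrations; re-solving the
    # concentrations once with full-axis columns removes that bias
    shift_map = {beliefs[c].cluster_id: float(final_delta[c]) for c in range(nc)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        exact = fit_concentrations(spectrum, lib, shift_map, profiled_mask=profiled)
    final_rho = np.minimum(
        np.array([exact[name] for name in comp_names]), rho_max
    )

    assign = ProfileAssignment(
        concentrations={name: float(r) for name, r in zip(comp_names, final_rho)},
        shifts={beliefs[c].cluster_id: float(final_delta[c]) for c in range(nc)},
    )
    diag = InferenceDiagnostics(
        converged, it, final_loss, loss_trace, belief_trace, rho_stats
    )
    return assign, diag
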