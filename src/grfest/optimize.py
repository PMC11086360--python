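"""Genetic-algorithm optimization of the reference-trajectory nodes.

A real-coded GA (tournament selection, simulated-binary crossover, Gaussian
mutation, elitism) searches the spline node values; each candidate is scored
by forward-simulating the model and evaluating the three-term cost against
the EKF-fused measurements.  With elitism the best cost per generation is
non-increasing, and a fixed seed reproduces the run bit-for-bit.

The initial population is seeded around an inverse-kinematics first guess
(joint angles read off the estimated segment orientations at the node
times) when one is supplied; this keeps modest population/generation budgets
effective on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body import BodyModel, JOINTS, ModelState
from .costs import CostBreakdown, CostWeights, cost_IQ, cost_Ia_pelvis, \
    cost_Imuscle, total_cost
from .dynamics import ControlGains, GroundParams, SimulationError, \
    SolverOptions, simulate
from .ekf import OrientationEstimate
from .quat import quat_conj, quat_multiply, to_scipy
from .reference import ReferenceTrajectory

PENALTY = 1e12


@dataclass
class GAConfig:
    population: int = 60
    generations: int = 100
    cx_prob: float = 0.9
    cx_eta: float = 15.0
    mut_prob: float = 0.5           # per-gene mutation probability
    sigma_rel: float = 1.0          # mutation scale relative to population spread
    tournament: int = 5
    n_polish: int = 8               # (1+1)-ES polish trials of the incumbent per generation
    elite: int = 2
    seed: int = 0
    init_sigma: float = 0.08        # rad, spread of the seeded population

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.elite >= self.population:
            raise ValueError("elite count must be below the population size")


@dataclass
class Measurements:
    """EKF-derived targets on the cost-evaluation grid."""

    t: np.ndarray                   # (T,) seconds, uniform (typically 100 Hz)
    segments: list[str]             # tracked segments (<= 12)
    seg_euler: np.ndarray           # (S, T, 3) X-Y-Z Euler, global frame
    pelvis_acc: np.ndarray          # (T, 3) specific force, pelvis sensor frame
    initial_state: ModelState | None = None


@dataclass
class OptResult:
    best: ReferenceTrajectory
    cost: CostBreakdown
    history_best: np.ndarray        # (G+1,) best-ever I_all per generation
    history_mean: np.ndarray
    n_evals: int
    failures: int


def evaluate_candidate(model: BodyModel, traj: ReferenceTrajectory,
                       meas: Measurements, weights: CostWeights,
                       gains: ControlGains, ground: GroundParams,
                       seg_idx: np.ndarray) -> tuple[CostBreakdown, object]:
    """Simulate one candidate and score it; simulation failures earn a
    penalty cost."""
    rate = 1.0 / (meas.t[1] - meas.t[0])
    opts = SolverOptions(method="semi_implicit", output_rate=rate)
    try:
        sim = simulate(model, traj, gains=gains, ground=ground,
                       t_span=(meas.t[0], meas.t[-1]), solver_opts=opts,
                       initial_state=meas.initial_state)
    except SimulationError:
        return CostBreakdown(PENALTY, PENALTY, PENALTY, PENALTY), None
    euler = sim.seg_euler()[seg_idx]
    dof = model.joint_dof_table()
    iq = cost_IQ(euler, meas.seg_euler, meas.t)
    ia = cost_Ia_pelvis(sim.pelvis_acc, meas.pelvis_acc, meas.t)
    im = cost_Imuscle(sim.tau_a, dof["tau_plus"], dof["tau_minus"], meas.t)
    return total_cost(iq, ia, im, weights), sim


def node_bounds(model: BodyModel, skeleton: ReferenceTrajectory):
    """Per-gene joint-limit bounds for the node vector."""
    dof = model.joint_dof_table()
    names = model.dof_names()
    lo, hi = [], []
    for k, nm in enumerate(skeleton.dof_names):
        i = names.index(nm)
        lo += [dof["q_min"][i]] * len(skeleton.node_values[k])
        hi += [dof["q_max"][i]] * len(skeleton.node_values[k])
    return np.array(lo), np.array(hi)


def ik_first_guess(model: BodyModel, est: OrientationEstimate,
                   skeleton: ReferenceTrajectory) -> np.ndarray:
    """Inverse-kinematics node guess: joint angles are the X-Y-Z Euler
    decomposition of each estimated parent->child relative rotation, sampled
    at the node times.  DOFs whose joint lacks an estimated pair stay 0."""
    angles = {}
    for jname, _b, pseg, cseg, _nd in JOINTS:
        if pseg in est.segments and cseg in est.segments:
            qp = est.quat[est.idx(pseg)]
            qc = est.quat[est.idx(cseg)]
            rel = np.empty((est.t.size, 4))
            for k in range(est.t.size):
                rel[k] = quat_multiply(quat_conj(qp[k]), qc[k])
            angles[jname] = to_scipy(rel).as_euler("XYZ")
    x = []
    for k, nm in enumerate(skeleton.dof_names):
        jname, ax = nm.rsplit("_", 1)
        vals = np.zeros(len(skeleton.node_times[k]))
        if jname in angles:
            d = model.joints[jname].dof_axes.index(ax)
            vals = np.interp(skeleton.node_times[k], est.t, angles[jname][:, d])
        x.append(vals)
    return np.concatenate(x)


def _sbx(rng, p1, p2, lo, hi, eta):
    """Simulated binary crossover (bounded)."""
    u = rng.random(p1.size)
    beta = np.where(u <= 0.5, (2 * u) ** (1.0 / (eta + 1)),
                    (1.0 / (2 * (1 - u))) ** (1.0 / (eta + 1)))
    c1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    c2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def ga_minimize(fun, lo: np.ndarray, hi: np.ndarray, ga: GAConfig,
                init_guess: np.ndarray | None = None, callback=None):
    """Generic bounded real-coded memetic GA.

    Tournament selection, simulated binary crossover, Gaussian mutation
    scaled to the current population spread with a 1/5-success global step
    adaptation, elitism, and a short (1+1)-ES polish of the incumbent each
    generation.  ``fun`` maps a vector to a scalar or a (scalar, payload)
    tuple; returns (best_x, best_val, history_best, history_mean, n_evals,
    payload_of_best)."""
    rng = np.random.default_rng(ga.seed)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    D = lo.size
    P = ga.population
    span = hi - lo

    def score(x):
        out = fun(x)
        val = out if np.isscalar(out) else out[0]
        return val, out

    pop = np.empty((P, D))
    if init_guess is not None:
        g = np.clip(np.asarray(init_guess, dtype=float), lo, hi)
        pop[0] = g
        for i in range(1, P):
            pop[i] = np.clip(g + ga.init_sigma * rng.standard_normal(D), lo, hi)
    else:
        pop = lo + span * rng.random((P, D))
    scored = [score(x) for x in pop]
    fitness = np.array([s[0] for s in scored])
    n_evals = P

    k0 = int(np.argmin(fitness))
    best_x = pop[k0].copy()
    best_f = fitness[k0]
    raw_best = scored[k0][1]
    hist_best = [best_f]
    hist_mean = [float(np.mean(np.minimum(fitness, PENALTY)))]
    scale = 1.0
    ps = 0.3

    for gen in range(ga.generations):
        order = np.argsort(fitness)
        elites = pop[order[:ga.elite]].copy()
        elite_scored = [scored[k] for k in order[:ga.elite]]
        sig = scale * ga.sigma_rel * pop.std(axis=0) + 1e-14
        children = []
        parent_of = []
        while len(children) < P - ga.elite:
            i1 = min(rng.integers(P, size=ga.tournament), key=lambda i: fitness[i])
            i2 = min(rng.integers(P, size=ga.tournament), key=lambda i: fitness[i])
            c1, c2 = pop[i1].copy(), pop[i2].copy()
            if rng.random() < ga.cx_prob:
                c1, c2 = _sbx(rng, pop[i1], pop[i2], lo, hi, ga.cx_eta)
            for c, ip in ((c1, i1), (c2, i2)):
                mask = rng.random(D) < ga.mut_prob
                c[mask] += sig[mask] * rng.standard_normal(int(mask.sum()))
                children.append(np.clip(c, lo, hi))
                parent_of.append(ip)
        children = children[:P - ga.elite]
        parent_of = parent_of[:P - ga.elite]
        child_scored = []
        for x in children:
            child_scored.append(score(x))
            n_evals += 1
        child_fit = np.array([s[0] for s in child_scored])
        success = float(np.mean(child_fit < fitness[np.array(parent_of)]))
        scale = min(max(scale * (1.25 if success > 0.25 else 0.85), 0.2), 5.0)

        pop = np.vstack([elites] + children)
        scored = list(elite_scored) + child_scored
        fitness = np.array([s[0] for s in scored])
        k = int(np.argmin(fitness))
        if fitness[k] < best_f:
            best_f = fitness[k]
            best_x = pop[k].copy()
            raw_best = scored[k][1]

        # (1+1)-ES polish of the incumbent, 1/5-success step control
        for _ in range(ga.n_polish):
            y = np.clip(best_x + ps * 0.05 * span * rng.standard_normal(D),
                        lo, hi)
            fy, raw_y = score(y)
            n_evals += 1
            if fy < best_f:
                best_f = fy
                best_x = y
                raw_best = raw_y
                ps *= 1.5
            else:
                ps *= 0.87
            ps = min(max(ps, 1e-5), 2.0)
        # the polished incumbent replaces the worst individual
        wi = int(np.argmax(fitness))
        pop[wi] = best_x
        fitness[wi] = best_f
        scored[wi] = (best_f, raw_best)

        hist_best.append(best_f)
        hist_mean.append(float(np.mean(np.minimum(fitness, PENALTY))))
        if callback is not None:
            callback(gen, best_f)

    return (best_x, best_f, np.array(hist_best), np.array(hist_mean),
            n_evals, raw_best)


def optimize(model: BodyModel, meas: Measurements,
             skeleton: ReferenceTrajectory,
             ga: GAConfig | None = None,
             weights: CostWeights | None = None,
             gains: ControlGains | None = None,
             ground: GroundParams | None = None,
             init_guess: np.ndarray | None = None,
             callback=None) -> OptResult:
    """Minimize the trajectory cost over the node values."""
    ga = ga or GAConfig()
    weights = weights or CostWeights()
    gains = gains or ControlGains()
    ground = ground or GroundParams()
    lo, hi = node_bounds(model, skeleton)
    from .body import SEGMENTS
    seg_idx = np.array([SEGMENTS.index(s) for s in meas.segments])
    failures = [0]

    def fun(x):
        bd, _ = evaluate_candidate(model, skeleton.with_vector(x), meas,
                                   weights, gains, ground, seg_idx)
        if bd.I_all >= PENALTY:
            failures[0] += 1
        return bd.I_all, bd

    best_x, best_f, hist_best, hist_mean, n_evals, raw = ga_minimize(
        fun, lo, hi, ga, init_guess=init_guess, callback=callback)
    if failures[0] == n_evals:
        raise SimulationError("every candidate simulation diverged")
    return OptResult(best=skeleton.with_vector(best_x), cost=raw[1],
                     history_best=hist_best, history_mean=hist_mean,
                     n_evals=n_evals, failures=failures[0])
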