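"""Lineage substitution rates and Bayesian divergence dating.

Two pieces of machinery live here.

*Functional-constraint-adjusted rates.*  MHC coding fragments do not evolve
neutrally, so a neutral genomic rate cannot be applied directly.  For a
supported allelic lineage, the synonymous distance dS of every sequence pair
is regressed (through the origin) on the pair's total distance; the slope —
the fraction of total divergence that is synonymous, an estimate of
functional constraint — multiplies a neutral genomic rate (zebra finch or
chicken) to give the lineage's adjusted rate in substitutions/site/My.

*Clock dating.*  ``ClockDating`` is a model object over a fixed rooted
topology: node ages (My), HKY kappa, discrete-gamma shape and the Yule birth
rate are sampled by Metropolis-Hastings under a strict, random-local or
relaxed-exponential clock, with the substitution rate fixed from the
adjusted rate.  ``fit()`` returns a ``DatingResults`` carrying the thinned
posterior trace, ESS/HPD summaries and per-clade TMRCA posteriors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlleleAlignment
from .codon import SaturationError
from .distances import encode, estimate_R, pairwise_distance
from .njtree import Node
from .stats import _codon_count_arrays, _jc

# previously estimated neutral nuclear mutation rates, substitutions/site/year
NEUTRAL_RATES = {"zebra_finch": 2.21e-9, "chicken": 1.91e-9}


# ---------------------------------------------------------------------------
# constraint slope and adjusted rate


@dataclass
class ConstraintFit:
    lineage_id: str
    points: list[tuple[float, float]]  # (d_total, d_syn) per pair
    slope: float
    neutral_rate: float | None = None  # subs/site/year
    adjusted_rate: float | None = None  # subs/site/My


def fit_origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on x constrained through the origin."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = float(np.sum(x * x))
    if denom == 0:
        raise ValueError("all x values zero: slope undefined")
    return float(np.sum(x * y) / denom)


def constraint_slope(
    aln: AlleleAlignment, R: float | None = None, lineage_id: str = ""
) -> ConstraintFit:
    """Origin-constrained regression of pairwise dS on total distance.

    x = Jukes-Cantor total distance, y = modified Nei-Gojobori dS, over all
    unordered pairs; slope = sum(xy)/sum(x^2).  A zero-divergence pair has
    zero dS, so the line passes through the origin by construction.
    """
    n = len(aln)
    if n < 3:
        raise ValueError("constraint slope needs >= 3 lineage members")
    if R is None:
        R = estimate_R(aln.seqs)
    ND, SD, NS, SS = _codon_count_arrays(aln.seqs, R, aln.frame_offset)
    ds = _jc(SD.sum(axis=1) / SS.sum(axis=1))
    xs = []
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_distance(aln.seqs[i], aln.seqs[j], model="jc")
            xs.append(d.d_jc)
            k += 1
    xs = np.asarray(xs)
    if np.isnan(ds).any():
        raise SaturationError("saturated pair in constraint regression")
    if np.all(xs == 0):
        raise ValueError("all pairs identical: slope undefined")
    slope = fit_origin_slope(xs, ds)
    return ConstraintFit(
        lineage_id=lineage_id,
        points=list(zip(xs.tolist(), ds.tolist())),
        slope=max(slope, 0.0),
    )


def adjusted_rate(fit: ConstraintFit, neutral_rate: float | str) -> float:
    """Adjusted substitution rate = slope x neutral rate, in subs/site/My.

    ``neutral_rate`` is substitutions/site/year (or the name of a packaged
    estimate: 'zebra_finch' or 'chicken').
    """
    if isinstance(neutral_rate, str):
        neutral_rate = NEUTRAL_RATES[neutral_rate]
    rate = fit.slope * neutral_rate * 1e6
    fit.neutral_rate = neutral_rate
    fit.adjusted_rate = rate
    return rate


# ---------------------------------------------------------------------------
# HKY + discrete gamma likelihood


_GAMMA_CACHE: dict[tuple[float, int], np.ndarray] = {}


def gamma_category_rates(shape: float, ncat: int = 4) -> np.ndarray:
    """Median-method discrete gamma rates, normalised to mean 1."""
    from scipy.special import gammaincinv

    key = (shape, ncat)
    r = _GAMMA_CACHE.get(key)
    if r is None:
        q = (2 * np.arange(ncat) + 1) / (2.0 * ncat)
        r = gammaincinv(shape, q) / shape
        r = r / r.mean()
        if len(_GAMMA_CACHE) > 4096:
            _GAMMA_CACHE.clear()
        _GAMMA_CACHE[key] = r
    return r


def hky_P(t: np.ndarray, kappa: float, freqs: np.ndarray) -> np.ndarray:
    """HKY transition probabilities for an array of branch lengths.

    ``t`` in expected substitutions/site (matrix normalised to unit mean
    rate); returns array of shape t.shape + (4, 4), base order A,C,G,T.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    pa, pc, pg, pt = freqs
    pR, pY = pa + pg, pc + pt
    beta = 0.5 / (pR * pY + kappa * (pa * pg + pc * pt))
    e1 = np.exp(-beta * t)[..., None, None]  # (..., 1, 1)
    group = np.array([pR, pY, pR, pY])
    e2 = np.exp(-beta * t[..., None] * (1.0 + group * (kappa - 1.0)))[..., None, :]
    fj = np.asarray(freqs)[None, :]
    gj = group[None, :]
    same = np.array(
        [[(i % 2) == (j % 2) for j in range(4)] for i in range(4)]
    )  # A,G purines at even indices; C,T pyrimidines at odd
    eye = np.eye(4, dtype=bool)
    base = fj + fj * (1.0 / gj - 1.0) * e1  # (..., 4, 4) via broadcast
    P = np.where(
        eye,
        base + ((gj - fj) / gj) * e2,
        np.where(same, base - (fj / gj) * e2, fj * (1.0 - e1)),
    )
    return P


def _compress_patterns(seq_arrays: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Site patterns and weights; columns stacked (n_taxa, L)."""
    mat = np.vstack(seq_arrays)
    pats, counts = np.unique(mat, axis=1, return_counts=True)
    return pats, counts.astype(float)


class _PruningEngine:
    """Felsenstein pruning over a fixed rooted topology (pattern-compressed)."""

    def __init__(self, tree: Node, aln: AlleleAlignment, ncat: int = 4):
        self.ncat = ncat
        seq_of = dict(zip(aln.labels, aln.seqs))
        # postorder node list; children indices; leaf pattern rows
        self.nodes: list[Node] = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [
            [self.index[id(c)] for c in n.children] for n in self.nodes
        ]
        leaves = [n for n in self.nodes if n.is_leaf]
        enc = [encode(seq_of[n.label]) for n in leaves]
        self.patterns, self.weights = _compress_patterns(enc)
        self.n_patterns = self.patterns.shape[1]
        leaf_rows = {id(n): r for r, n in enumerate(leaves)}
        # leaf tip partials: (node) -> (npat,4) one-hot with N as all-ones
        self.tip_partials: dict[int, np.ndarray] = {}
        self.tip_index: dict[int, np.ndarray | None] = {}
        for n in leaves:
            row = self.patterns[leaf_rows[id(n)]]
            tp = np.zeros((self.n_patterns, 4))
            for p, b in enumerate(row):
                if b < 0:
                    tp[p, :] = 1.0
                else:
                    tp[p, b] = 1.0
            i = self.index[id(n)]
            self.tip_partials[i] = tp
            # ambiguity-free tips admit a cheap fancy-indexing pruning step
            self.tip_index[i] = row.copy() if (row >= 0).all() else None
        counts = np.zeros(4)
        for e in enc:
            counts += np.bincount(e[e >= 0], minlength=4)
        self.freqs = (counts + 1.0) / (counts.sum() + 4.0)
        # cached coefficient matrices for the analytic HKY form:
        # P = A + B*e1 + C*e2(group of j); depends only on base frequencies
        f = self.freqs
        group = np.array([f[0] + f[2], f[1] + f[3], f[0] + f[2], f[1] + f[3]])
        A = np.tile(f, (4, 1))
        B = np.empty((4, 4))
        C = np.empty((4, 4))
        same = np.array([[(i % 2) == (j % 2) for j in range(4)] for i in range(4)])
        for j in range(4):
            fj, gj = f[j], group[j]
            for i in range(4):
                if i == j:
                    B[i, j] = fj * (1.0 / gj - 1.0)
                    C[i, j] = (gj - fj) / gj
                elif same[i, j]:
                    B[i, j] = fj * (1.0 / gj - 1.0)
                    C[i, j] = -fj / gj
                else:
                    B[i, j] = -fj
                    C[i, j] = 0.0
        self._ABC = (A, B, C)
        self._jmap = np.array([0, 1, 0, 1])  # purine/pyrimidine group per column

    def _P(self, t_eff: np.ndarray, kappa: float) -> np.ndarray:
        """Analytic HKY transition matrices, shape t_eff.shape + (4, 4)."""
        f = self.freqs
        pR, pY = f[0] + f[2], f[1] + f[3]
        beta = 0.5 / (pR * pY + kappa * (f[0] * f[2] + f[1] * f[3]))
        A, B, C = self._ABC
        e1 = np.exp(-beta * t_eff)
        e2 = np.exp(
            -beta
            * t_eff[..., None]
            * np.array([1.0 + pR * (kappa - 1.0), 1.0 + pY * (kappa - 1.0)])
        )
        E2 = e2[..., self._jmap]
        return A + B * e1[..., None, None] + C * E2[..., None, :]

    def loglik(self, branch_subs: np.ndarray, kappa: float, shape: float) -> float:
        """branch_subs[i] = expected substitutions/site on the branch above
        node i (root entry ignored)."""
        rates = gamma_category_rates(shape, self.ncat)  # (ncat,)
        # per node per category P matrices
        t_eff = branch_subs[:, None] * rates[None, :]  # (nodes, ncat)
        P = self._P(t_eff, kappa)  # (nodes, ncat, 4, 4)
        partials: list[np.ndarray | None] = [None] * len(self.nodes)
        for i, ch in enumerate(self.children):
            if not ch:
                continue
            acc = None
            for c in ch:
                cp = partials[c]
                if cp is None:  # leaf
                    idx = self.tip_index[c]
                    if idx is not None:
                        # contrib[cat, p, j] = P[j -> tip_base(p)]
                        contrib = P[c][:, :, idx].transpose(0, 2, 1)
                        acc = contrib if acc is None else acc * contrib
                        continue
                    cp = np.broadcast_to(
                        self.tip_partials[c], (self.ncat, self.n_patterns, 4)
                    )
                contrib = np.matmul(cp, P[c].transpose(0, 2, 1))  # (ncat,npat,4)
                acc = contrib if acc is None else acc * contrib
            partials[i] = acc
        root = partials[-1]
        site_l = (partials[-1] @ self.freqs).mean(axis=0)
        if np.any(site_l <= 0):
            return -np.inf
        return float(self.weights @ np.log(site_l))


# ---------------------------------------------------------------------------
# clock configuration and results


@dataclass
class ClockConfig:
    clock: str = "strict"  # strict | random_local | relaxed_exponential
    rate: float = 2.21e-3  # subs/site/My, fixed from the adjusted rate
    gamma_categories: int = 4
    generations: int = 100_000
    burnin: int | None = None  # default: 10% of generations
    thin: int | None = None  # default: generations // 2000
    yule_rate: float | None = None  # None: sampled
    seed: int = 0
    likelihood_off: bool = False  # sample from the prior only
    rlc_change_prob: float | None = None  # default ln2 / n_branches
    rlc_sigma: float = 0.7  # lognormal sd of local rate multipliers

    def __post_init__(self):
        if self.clock not in ("strict", "random_local", "relaxed_exponential"):
            raise ValueError(f"unknown clock {self.clock!r}")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        b = self.burnin if self.burnin is not None else self.generations // 10
        if not 0 <= b < self.generations:
            raise ValueError("need generations > burnin >= 0")


@dataclass
class PosteriorTrace:
    samples: pd.DataFrame  # thinned post-burnin samples, col 0 = state
    summaries: pd.DataFrame
    acceptance: dict[str, float]
    unreliable: bool  # any parameter ESS < 100

    def to_log(self, path) -> None:
        """Tab-separated trace log (column 1 = state index)."""
        self.samples.to_csv(path, sep="\t", index=False)


class DatingResults:
    """Posterior summaries from a fitted ClockDating model."""

    def __init__(self, model: "ClockDating", trace: PosteriorTrace):
        self.model = model
        self.trace = trace
        self.samples = trace.samples
        self.unreliable = trace.unreliable

    def summary(self) -> pd.DataFrame:
        return self.trace.summaries

    def hpd(self, param: str, level: float = 0.95) -> tuple[float, float]:
        return hpd_interval(self.samples[param].to_numpy(), level)

    def ess(self, param: str) -> float:
        return effective_sample_size(self.samples[param].to_numpy())

    def tmrca(self, clade: str) -> pd.Series:
        return self.samples[f"tmrca_{clade}"]

    def dated_newick(self) -> str:
        """Newick of the fixed topology with posterior-mean node ages
        (branch lengths in My, ages annotated as comments)."""
        model = self.model
        ages = model.mean_node_ages
        idx = model.engine.index

        def fmt(node, parent_age):
            a = ages[idx[id(node)]]
            bl = max(parent_age - a, 0.0)
            if node.is_leaf:
                return f"{node.label}[&age={a:.4g}]:{bl:.6g}"
            inner = ",".join(fmt(c, a) for c in node.children)
            return f"({inner})[&age={a:.4g}]:{bl:.6g}"

        root = model.nodes[-1]
        root_age = ages[idx[id(root)]]
        inner = ",".join(fmt(c, root_age) for c in root.children)
        return f"({inner})[&age={root_age:.4g}];"

    def plot_trace(self, params=None):  # pragma: no cover - visual aid
        import matplotlib.pyplot as plt

        params = params or [c for c in self.samples.columns if c != "state"][:6]
        fig, axes = plt.subplots(len(params), 1, figsize=(7, 2 * len(params)))
        for ax, p in zip(np.atleast_1d(axes), params):
            ax.plot(self.samples["state"], self.samples[p], lw=0.5)
            ax.set_ylabel(p)
        return fig


# ---------------------------------------------------------------------------
# trace summaries


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via Geyer's initial monotone positive sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    v = float(np.dot(x, x)) / n
    if v == 0 or n < 4:
        return float(n)
    acov = np.correlate(x, x, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    # pair sums Gamma_m = rho_{2m} + rho_{2m+1}
    m_max = (n - 1) // 2
    gam = rho[0 : 2 * m_max : 2] + rho[1 : 2 * m_max : 2]
    tau = -1.0
    prev = np.inf
    for g in gam:
        if g <= 0:
            break
        g = min(g, prev)  # enforce monotone decrease
        prev = g
        tau += 2.0 * g
    tau = max(tau, 1e-12)
    return float(min(n, n / tau))


def hpd_interval(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``level`` of the samples."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    m = max(1, int(math.ceil(level * n)))
    if m >= n:
        return float(xs[0]), float(xs[-1])
    widths = xs[m - 1 :] - xs[: n - m + 1]
    k = int(np.argmin(widths))
    return float(xs[k]), float(xs[k + m - 1])


def trace_summary(samples: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Per-parameter mean, SD, SE (SD/sqrt(ESS)), ESS and HPD bounds."""
    if len(samples) < 100:
        raise ValueError("need >= 100 post-burnin samples")
    rows = []
    for col in samples.columns:
        if col == "state":
            continue
        x = samples[col].to_numpy(dtype=float)
        ess = effective_sample_size(x)
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        lo, hi = hpd_interval(x, level)
        rows.append(
            {
                "parameter": col,
                "mean": float(np.mean(x)),
                "sd": sd,
                "se": sd / math.sqrt(max(ess, 1e-12)),
                "ess": ess,
                f"hpd{int(level * 100)}_low": lo,
                f"hpd{int(level * 100)}_high": hi,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# the model object


class ClockDating:
    """Bayesian node-age sampling on a fixed topology.

    Parameters
    ----------
    aln : gap-free alignment of the taxa to date.
    tree : rooted topology over the alignment labels (branch lengths are
        ignored; ages are initialised from the clock rate and sequence
        divergence, then sampled).
    config : ClockConfig with the clock model and fixed substitution rate.
    clades : mapping name -> leaf-label set; each must be monophyletic in
        ``tree`` and its TMRCA is traced.
    mrca_groups : mapping name -> leaf-label set; the age of the MRCA node
        is traced without requiring monophyly (used for lineage dyads).
    """

    def __init__(
        self,
        aln: AlleleAlignment,
        tree: Node,
        config: ClockConfig,
        clades: dict[str, set[str]] | None = None,
        mrca_groups: dict[str, set[str]] | None = None,
    ):
        self.aln = aln
        self.config = config
        self.tree = tree.copy()
        labels = {n.label for n in self.tree.leaves()}
        if labels != set(aln.labels):
            missing = labels.symmetric_difference(aln.labels)
            raise ValueError(f"tree/alignment label mismatch: {sorted(missing)[:5]}")
        self.engine = _PruningEngine(self.tree, aln, ncat=config.gamma_categories)
        self.nodes = self.engine.nodes  # postorder; root last
        self.n_nodes = len(self.nodes)
        self.parent = np.full(self.n_nodes, -1)
        for i, ch in enumerate(self.engine.children):
            for c in ch:
                self.parent[c] = i
        self.internal = [i for i, n in enumerate(self.nodes) if not n.is_leaf]
        self.leafset = [frozenset(n.leaf_labels()) for n in self.nodes]
        self.n_leaves = sum(1 for n in self.nodes if n.is_leaf)

        self.clade_nodes: dict[str, int] = {}
        for name, members in (clades or {}).items():
            i = self._mrca(members)
            if self.leafset[i] != frozenset(members):
                raise ValueError(f"clade {name!r} is not monophyletic in the tree")
            self.clade_nodes[name] = i
        self.group_nodes: dict[str, int] = {
            name: self._mrca(members) for name, members in (mrca_groups or {}).items()
        }

    def _mrca(self, members) -> int:
        members = frozenset(members)
        if not members <= self.leafset[-1]:
            raise ValueError("clade contains labels absent from the tree")
        best = None
        for i in range(self.n_nodes):
            if members <= self.leafset[i]:
                if best is None or len(self.leafset[i]) < len(self.leafset[best]):
                    best = i
        return best

    # -- initial state ------------------------------------------------------

    def _init_ages(self, rng) -> np.ndarray:
        ages = np.zeros(self.n_nodes)
        for i in self.internal:
            ch = self.engine.children[i]
            ages[i] = max(ages[c] for c in ch) + 1.0 + rng.random()
        return ages

    # -- priors -------------------------------------------------------------

    def _log_prior(self, ages, kappa, shape, lam, state) -> float:
        cfg = self.config
        lp = 0.0
        # Yule pure-birth density over node times: (n-1) log lam - lam * L
        L = 0.0
        for i in range(self.n_nodes - 1):
            L += ages[self.parent[i]] - ages[i]
        lp += (self.n_leaves - 1) * math.log(lam) - lam * L
        if cfg.yule_rate is None:
            lp += -lam / 0.05  # diffuse exponential birth-rate hyperprior (mean 0.05/My)
            if not 1e-6 < lam < 1e3:
                return -np.inf
        # kappa ~ LogNormal(1, 1.25); shape ~ Exponential(1)
        lp += -((math.log(kappa) - 1.0) ** 2) / (2 * 1.25**2) - math.log(kappa)
        lp += -shape
        if kappa <= 0 or shape <= 0.02 or shape > 300:
            return -np.inf
        if cfg.clock == "relaxed_exponential":
            # iid exponential branch rates, mean = cfg.rate
            r = state["branch_rates"]
            lp += float(np.sum(-r / cfg.rate - math.log(cfg.rate)))
            if np.any(r <= 0):
                return -np.inf
        elif cfg.clock == "random_local":
            p = cfg.rlc_change_prob
            if p is None:
                p = min(0.5, math.log(2.0) / max(self.n_nodes - 1, 1))
            I = state["indicators"]
            m = state["multipliers"]
            k = int(I.sum())
            lp += k * math.log(p) + (self.n_nodes - 1 - k) * math.log(1 - p)
            lp += float(
                np.sum(
                    -(np.log(m) ** 2) / (2 * self.config.rlc_sigma**2) - np.log(m)
                )
            )
            if np.any(m <= 0):
                return -np.inf
        return lp

    # -- branch substitution lengths ----------------------------------------

    def _branch_subs(self, ages, state) -> np.ndarray:
        cfg = self.config
        dur = np.zeros(self.n_nodes)
        for i in range(self.n_nodes - 1):
            dur[i] = ages[self.parent[i]] - ages[i]
        if cfg.clock == "strict":
            return dur * cfg.rate
        if cfg.clock == "relaxed_exponential":
            return dur * state["branch_rates"]
        # random local clock: rate multiplier accumulates root-to-tip
        eff = np.empty(self.n_nodes)
        eff[-1] = cfg.rate
        for i in range(self.n_nodes - 2, -1, -1):
            r = eff[self.parent[i]]
            if state["indicators"][i]:
                r = r * state["multipliers"][i]
            eff[i] = r
        return dur * eff

    # -- fitting -------------------------------------------------------------

    def fit(self) -> DatingResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        burnin = cfg.burnin if cfg.burnin is not None else cfg.generations // 10
        thin = cfg.thin if cfg.thin is not None else max(1, cfg.generations // 2000)

        ages = self._init_ages(rng)
        kappa, shape = 2.0, 1.0
        lam = cfg.yule_rate if cfg.yule_rate is not None else 0.05
        state = {
            "branch_rates": np.full(self.n_nodes, cfg.rate),
            "indicators": np.zeros(self.n_nodes, dtype=bool),
            "multipliers": np.ones(self.n_nodes),
        }

        def loglik() -> float:
            if cfg.likelihood_off:
                return 0.0
            return self.engine.loglik(self._branch_subs(ages, state), kappa, shape)

        lp = self._log_prior(ages, kappa, shape, lam, state)
        ll = loglik()
        scales = {"age": 1.0, "root": 0.3, "scale_all": 0.2, "kappa": 0.3,
                  "shape": 0.3, "lam": 0.5, "rate": 0.4, "mult": 0.4}
        moves = ["age", "age", "age", "root", "scale_all", "kappa", "shape"]
        if cfg.yule_rate is None:
            moves.append("lam")
        if cfg.clock == "relaxed_exponential":
            moves += ["rate", "rate"]
        elif cfg.clock == "random_local":
            moves += ["flip", "mult"]
        att = {m: 0 for m in moves}
        acc = {m: 0 for m in moves}

        records = []
        age_accum = np.zeros(self.n_nodes)
        n_rec = 0
        for it in range(cfg.generations):
            mv = moves[int(rng.integers(0, len(moves)))]
            att[mv] += 1
            log_hastings = 0.0
            new_ages = ages
            nk, ns, nl = kappa, shape, lam
            new_state = state
            likelihood_changed = True

            if mv == "age" and len(self.internal) > 1:
                i = self.internal[int(rng.integers(0, len(self.internal) - 1))]
                lo = max(ages[c] for c in self.engine.children[i])
                hi = ages[self.parent[i]]
                new_ages = ages.copy()
                new_ages[i] = lo + rng.random() * (hi - lo)
            elif mv in ("age", "root"):
                x = math.exp(scales["root"] * (rng.random() - 0.5))
                new_ages = ages.copy()
                root = self.n_nodes - 1
                lo = max(ages[c] for c in self.engine.children[root])
                new_ages[root] = lo + (ages[root] - lo) * x
                log_hastings = math.log(x)
            elif mv == "scale_all":
                x = math.exp(scales["scale_all"] * (rng.random() - 0.5))
                new_ages = ages.copy()
                for i in self.internal:
                    new_ages[i] = ages[i] * x
                log_hastings = len(self.internal) * math.log(x)
            elif mv == "kappa":
                x = math.exp(scales["kappa"] * (rng.random() - 0.5))
                nk = kappa * x
                log_hastings = math.log(x)
            elif mv == "shape":
                x = math.exp(scales["shape"] * (rng.random() - 0.5))
                ns = shape * x
                log_hastings = math.log(x)
            elif mv == "lam":
                x = math.exp(scales["lam"] * (rng.random() - 0.5))
                nl = lam * x
                log_hastings = math.log(x)
                likelihood_changed = False
            elif mv == "rate":
                b = int(rng.integers(0, self.n_nodes - 1))
                x = math.exp(scales["rate"] * (rng.random() - 0.5))
                new_state = {**state, "branch_rates": state["branch_rates"].copy()}
                new_state["branch_rates"][b] *= x
                log_hastings = math.log(x)
            elif mv == "flip":
                b = int(rng.integers(0, self.n_nodes - 1))
                new_state = {**state, "indicators": state["indicators"].copy()}
                new_state["indicators"][b] = ~new_state["indicators"][b]
            elif mv == "mult":
                b = int(rng.integers(0, self.n_nodes - 1))
                x = math.exp(scales["mult"] * (rng.random() - 0.5))
                new_state = {**state, "multipliers": state["multipliers"].copy()}
                new_state["multipliers"][b] *= x
                log_hastings = math.log(x)
                likelihood_changed = bool(state["indicators"][b])

            new_lp = self._log_prior(new_ages, nk, ns, nl, new_state)
            if not np.isfinite(new_lp):
                new_ll = -np.inf
            elif likelihood_changed or cfg.likelihood_off:
                if cfg.likelihood_off:
                    new_ll = 0.0
                else:
                    new_ll = self.engine.loglik(
                        self._branch_subs(new_ages, new_state), nk, ns
                    )
            else:
                new_ll = ll
            delta = (new_lp + new_ll) - (lp + ll) + log_hastings
            if np.isfinite(new_lp) and math.log(rng.random() + 1e-300) < delta:
                ages, kappa, shape, lam, state = new_ages, nk, ns, nl, new_state
                lp, ll = new_lp, new_ll
                acc[mv] += 1
            # adapt proposal scales during burnin, then freeze
            if it < burnin and it and it % 200 == 0:
                for m in moves:
                    if m in scales and att[m] >= 20:
                        r = acc[m] / att[m]
                        if r < 0.2:
                            scales[m] = max(scales[m] * 0.8, 1e-3)
                        elif r > 0.5:
                            scales[m] = min(scales[m] * 1.25, 20.0)
            if it >= burnin and (it - burnin) % thin == 0:
                age_accum += ages
                n_rec += 1
                rec = {
                    "state": it,
                    "posterior": lp + ll,
                    "likelihood": ll,
                    "prior": lp,
                    "root_age": ages[-1],
                    "kappa": kappa,
                    "gamma_shape": shape,
                    "yule_rate": lam,
                }
                if cfg.clock == "random_local":
                    rec["n_rate_changes"] = int(state["indicators"].sum())
                if cfg.clock == "relaxed_exponential":
                    rec["mean_branch_rate"] = float(state["branch_rates"][:-1].mean())
                for name, i in self.clade_nodes.items():
                    rec[f"tmrca_{name}"] = ages[i]
                for name, i in self.group_nodes.items():
                    rec[f"tmrca_{name}"] = ages[i]
                records.append(rec)

        samples = pd.DataFrame(records)
        summaries = trace_summary(samples) if len(samples) >= 100 else pd.DataFrame()
        ess_ok = True
        if len(summaries):
            core = [p for p in summaries.index if p not in ("prior", "posterior")]
            ess_ok = bool((summaries.loc[core, "ess"] >= 100).all())
        trace = PosteriorTrace(
            samples=samples,
            summaries=summaries,
            acceptance={m: (acc[m] / att[m] if att[m] else 0.0) for m in moves},
            unreliable=not ess_ok,
        )
        self.mean_node_ages = age_accum / max(n_rec, 1)
        return DatingResults(self, trace)


def mcmc_date(
    aln: AlleleAlignment,
    start_tree: Node,
    cfg: ClockConfig,
    clade_definitions: dict[str, set[str]] | None = None,
    mrca_groups: dict[str, set[str]] | None = None,
) -> DatingResults:
    """Functional wrapper over :class:`ClockDating`."""
    return ClockDating(aln, start_tree, cfg, clade_definitions, mrca_groups).fit()


# ---------------------------------------------------------------------------
# lineage dyad divergence times


def lineage_divergence_times(
    aln: AlleleAlignment,
    lineages,
    avg_rate: float,
    cfg: ClockConfig,
    tree: Node | None = None,
) -> tuple[pd.DataFrame, DatingResults]:
    """TMRCA table for every lineage pair plus the all-lineage MRCA.

    One chain over the pooled members under the average adjusted rate; each
    lineage is a strict (monophyletic) clade, each unordered pair and the
    full union are traced as MRCA groups.
    """
    from .njtree import midpoint_root, nj_tree
    from .distances import distance_matrix

    if len(lineages) < 2:
        raise ValueError("need >= 2 lineages")
    members = {ln.id: set(ln.members) for ln in lineages}
    keep = sorted(set().union(*members.values()))
    idx = [aln.labels.index(m) for m in keep]
    sub = aln.subset(idx)
    if tree is None:
        D = distance_matrix(sub.seqs, model="k2")
        tree = midpoint_root(nj_tree(D, sub.labels))
    groups = {}
    ids = sorted(members)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            groups[f"{ids[a]}-{ids[b]}"] = members[ids[a]] | members[ids[b]]
    groups["all"] = set(keep)
    cfg2 = ClockConfig(**{**cfg.__dict__, "rate": avg_rate})
    res = mcmc_date(sub, tree, cfg2, clade_definitions=members, mrca_groups=groups)
    rows = []
    for name in list(members) + list(groups):
        s = res.tmrca(name).to_numpy()
        lo, hi = hpd_interval(s, 0.95)
        rows.append(
            {"clade": name, "mean_tmrca_my": float(s.mean()),
             "hpd95_low": lo, "hpd95_high": hi,
             "ess": effective_sample_size(s)}
        )
    return pd.DataFrame(rows), res


# ---------------------------------------------------------------------------
# parsimony ancestral states


def fitch_ancestral(tree: Node, tip_states: dict[str, str], per_site: bool = False):
    """Fitch two-pass parsimony on a rooted cladogram.

    ``tip_states``: leaf label -> categorical state (e.g. lineage id), or,
    with ``per_site=True``, an equal-length sequence scored site by site and
    summed.  Returns (state_sets, score): state_sets lists each node's
    first-pass state set in postorder (per-site lists in sequence mode).
    """
    leaves = tree.leaves()
    for lf in leaves:
        if lf.label not in tip_states:
            raise ValueError(f"unlabeled tip {lf.label!r}")
    vals = list(tip_states.values())
    seq_mode = per_site
    if seq_mode and len({len(v) for v in vals}) != 1:
        raise ValueError("per-site mode needs equal-length sequences")

    def one_site(states: dict[str, str]):
        sets: list[set] = []
        score = 0

        def down(node: Node) -> set:
            nonlocal score
            if node.is_leaf:
                s = {states[node.label]}
            else:
                child_sets = [down(c) for c in node.children]
                s = set.intersection(*child_sets)
                if not s:
                    s = set.union(*child_sets)
                    score += len(child_sets) - 1 if len(child_sets) > 2 else 1
            sets.append(s)
            return s

        down(tree)
        return sets, score

    if seq_mode:
        L = len(vals[0])
        total = 0
        per_site_sets = None
        for j in range(L):
            sets, sc = one_site({k: v[j] for k, v in tip_states.items()})
            total += sc
            if per_site_sets is None:
                per_site_sets = [[s] for s in sets]
            else:
                for k, s in enumerate(sets):
                    per_site_sets[k].append(s)
        return per_site_sets, total
    sets, score = one_site(tip_states)
    return sets, score


def jc_marginal_ancestral(
    tree: Node, tip_states: dict[str, str], branch_length: float = 0.1
):
    """Secondary reconstruction: marginal ML root state probabilities under
    a Jukes-Cantor-style equal-rates model on the cladogram (every edge the
    same length).  Returns {state: posterior probability} at the root."""
    states = sorted(set(tip_states.values()))
    k = len(states)
    sindex = {s: i for i, s in enumerate(states)}
    p_same = 1.0 / k + (1.0 - 1.0 / k) * math.exp(-branch_length * k / (k - 1))
    p_diff = (1.0 - p_same) / (k - 1)
    P = np.full((k, k), p_diff)
    np.fill_diagonal(P, p_same)

    def partial(node: Node) -> np.ndarray:
        if node.is_leaf:
            v = np.zeros(k)
            v[sindex[tip_states[node.label]]] = 1.0
            return v
        out = np.ones(k)
        for c in node.children:
            out = out * (P @ partial(c))
        return out

    root = partial(tree) / k
    post = root / root.sum()
    return {s: float(post[sindex[s]]) for s in states}


__all__ = [
    "NEUTRAL_RATES",
    "ConstraintFit",
    "constraint_slope",
    "adjusted_rate",
    "ClockConfig",
    "ClockDating",
    "DatingResults",
    "PosteriorTrace",
    "mcmc_date",
    "lineage_divergence_times",
    "trace_summary",
    "effective_sample_size",
    "hpd_interval",
    "hky_P",
    "gamma_category_rates",
    "fitch_ancestral",
    "jc_marginal_ancestral",
]
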