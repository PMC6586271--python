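"""Bayesian admixture-model clustering by Gibbs sampling.

The model is the classic no-admixture-prior-free clustering model: each
individual i carries admixture proportions q_i over k clusters (Dirichlet
prior with uniform concentration alpha); each cluster has per-locus allele
frequencies with a Dirichlet(lambda) prior; every allele copy of every
genotype originates from a latent cluster drawn from q_i.  The Gibbs sweep
alternates the latent origins, the cluster frequencies and the admixture
proportions.  No geographic or population labels enter the model.

Organised statsmodels-style: build an :class:`AdmixtureModel` from a
:class:`~mixstock.io.GenotypeMatrix`, call :meth:`~AdmixtureModel.fit`, and
work with the returned :class:`AdmixtureResults`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

__all__ = ["AdmixtureModel", "AdmixtureResults", "run_replicates",
           "align_replicates", "evanno_delta_k", "call_assignments",
           "AssignmentResult"]


class AdmixtureModel:
    """Admixture-model clustering of diploid biallelic genotypes.

    Parameters
    ----------
    g : GenotypeMatrix
        Genotype data; missing calls contribute nothing to the likelihood.
    k : int
        Number of clusters (>= 1).
    alpha : float
        Dirichlet concentration of the admixture prior, uniform across
        clusters and fixed during sampling (no alpha update).  The small
        default emulates the concentration that likelihood-based tuning
        converges to for well-separated stocks and lets the posterior-mean
        q of an unambiguous individual approach 1.
    lam : float
        Dirichlet (Beta) concentration of the cluster allele-frequency prior.
    """

    def __init__(self, g: GenotypeMatrix, k: int, alpha: float = 0.1,
                 lam: float = 1.0):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.g = g
        self.k = int(k)
        self.alpha = float(alpha)
        self.lam = float(lam)
        calls = g.calls
        self._ok = calls != MISSING
        self._n_alt = np.where(self._ok, calls, 0).astype(np.int64)  # alt copies
        self._n_ref = np.where(self._ok, 2 - calls, 0).astype(np.int64)
        n_distinct = len({tuple(row) for row in calls})
        if k > n_distinct:
            import warnings
            warnings.warn(
                f"k={k} exceeds the {n_distinct} distinct multilocus genotypes",
                stacklevel=2)

    # -- likelihood --------------------------------------------------------

    def loglike(self, q: np.ndarray, p: np.ndarray) -> float:
        """Data log-likelihood at admixture proportions ``q`` (n, k) and
        cluster alt-allele frequencies ``p`` (k, L): per copy, the alt
        probability is the q-mixture of cluster frequencies."""
        w = np.clip(q @ p, 1e-12, 1 - 1e-12)
        calls = self.g.calls
        ll = np.where(calls == 0, 2 * np.log1p(-w),
                      np.where(calls == 1, math.log(2) + np.log(w) + np.log1p(-w),
                               2 * np.log(w)))
        return float(np.where(self._ok, ll, 0.0).sum())

    # -- Gibbs sweep -------------------------------------------------------

    def _sample_origins(self, q, p, rng):
        """Draw cluster origins for every allele copy; return per-individual
        origin counts m (n, k) and per-cluster allele counts (k, L) x 2."""
        n, L, k = self.g.n_individuals, self.g.n_loci, self.k
        m = np.zeros((n, k))
        alt_counts = np.zeros((k, L))
        ref_counts = np.zeros((k, L))
        # unnormalized membership weights per copy type
        log_q = np.log(np.clip(q, 1e-300, None))[:, None, :]          # (n,1,k)
        for counts_mat, tally, logp in (
                (self._n_alt, alt_counts, np.log(np.clip(p, 1e-300, None))),
                (self._n_ref, ref_counts, np.log(np.clip(1 - p, 1e-300, None)))):
            logw = log_q + logp.T[None, :, :]                          # (n,L,k)
            for copy in (0, 1):
                exists = counts_mat > copy
                if not exists.any():
                    continue
                gumb = rng.gumbel(size=(n, L, k))
                z = np.argmax(logw + gumb, axis=2)                     # (n,L)
                for kk in range(k):
                    hit = exists & (z == kk)
                    m[:, kk] += hit.sum(axis=1)
                    tally[kk] += hit.sum(axis=0)
        return m, alt_counts, ref_counts

    def fit(self, burn_in: int = 10_000, n_mcmc: int = 100_000,
            seed: int | np.random.Generator | None = None,
            thin: int = 10) -> "AdmixtureResults":
        """Run the Gibbs sampler: ``burn_in`` discarded sweeps followed by
        ``n_mcmc`` sweeps, recording every ``thin``-th post-burn-in state.

        Returns posterior means of q and the cluster frequencies together
        with the recorded log-likelihood trace.
        """
        rng = np.random.default_rng(seed)
        n, L, k = self.g.n_individuals, self.g.n_loci, self.k
        # initial state from the priors
        q = rng.dirichlet(np.full(k, self.alpha), size=n)
        p = rng.beta(self.lam, self.lam, size=(k, L))
        q_sum = np.zeros_like(q)
        p_sum = np.zeros_like(p)
        trace = []
        n_rec = 0
        for it in range(burn_in + n_mcmc):
            m, alt_c, ref_c = self._sample_origins(q, p, rng)
            p = rng.beta(self.lam + alt_c, self.lam + ref_c)
            gam = rng.gamma(self.alpha + m, 1.0)
            q = gam / gam.sum(axis=1, keepdims=True)
            if it >= burn_in and (it - burn_in) % thin == 0:
                q_sum += q
                p_sum += p
                trace.append(self.loglike(q, p))
                n_rec += 1
        if n_rec == 0:
            raise ValueError("no post-burn-in samples recorded; increase n_mcmc")
        return AdmixtureResults(
            model=self, k=k, q=q_sum / n_rec, cluster_freqs=p_sum / n_rec,
            ln_lik_trace=np.asarray(trace),
            settings={"burn_in": burn_in, "n_mcmc": n_mcmc, "thin": thin,
                      "alpha": self.alpha, "lambda": self.lam,
                      "seed": seed if isinstance(seed, int) else None})


@dataclass
class AdmixtureResults:
    """Posterior summaries of one admixture-model run."""

    model: AdmixtureModel
    k: int
    q: np.ndarray                 # (n, k) posterior-mean admixture proportions
    cluster_freqs: np.ndarray     # (k, L) posterior-mean alt-allele frequencies
    ln_lik_trace: np.ndarray
    settings: dict

    @property
    def ln_prob_data(self) -> float:
        """Harmonic-style model evidence estimate used for model choice
        across k: mean(ln L) - var(ln L)/2 over the recorded trace."""
        t = self.ln_lik_trace
        v = float(np.var(t, ddof=1)) if t.size > 1 else 0.0
        return float(t.mean() - v / 2.0)

    def q_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.q, index=self.model.g.individuals,
                          columns=[f"q{c + 1}" for c in range(self.k)])
        df.index.name = "individual"
        return df

    def summary(self) -> str:
        lines = [
            f"Admixture model, k={self.k}",
            f"  individuals: {self.model.g.n_individuals}, "
            f"loci: {self.model.g.n_loci}",
            f"  burn-in {self.settings['burn_in']}, "
            f"MCMC {self.settings['n_mcmc']}, thin {self.settings['thin']}",
            f"  mean ln L = {self.ln_lik_trace.mean():.1f}",
            f"  ln P(D) estimate = {self.ln_prob_data:.1f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, order_by_q: bool = True):
        """Stacked-bar plot of admixture proportions (one bar per
        individual)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2.5))
        q = self.q
        idx = np.argsort(-q[:, 0], kind="stable") if order_by_q else np.arange(len(q))
        bottom = np.zeros(len(q))
        x = np.arange(len(q))
        for c in range(self.k):
            ax.bar(x, q[idx, c], bottom=bottom, width=1.0, label=f"cluster {c + 1}")
            bottom += q[idx, c]
        ax.set_xlim(-0.5, len(q) - 0.5)
        ax.set_ylim(0, 1)
        ax.set_ylabel("q")
        ax.legend(loc="upper right", fontsize="small")
        return ax


def run_replicates(g: GenotypeMatrix, k: int, n_replicates: int = 10,
                   burn_in: int = 10_000, n_mcmc: int = 100_000,
                   seed: int | None = None, thin: int = 10,
                   alpha: float = 0.1, lam: float = 1.0) -> list[AdmixtureResults]:
    """Independent replicate runs at a single k with split random streams."""
    ss = np.random.SeedSequence(seed)
    model = AdmixtureModel(g, k, alpha=alpha, lam=lam)
    return [model.fit(burn_in=burn_in, n_mcmc=n_mcmc, thin=thin,
                      seed=np.random.default_rng(child))
            for child in ss.spawn(n_replicates)]


def align_replicates(runs: Sequence[AdmixtureResults] | Sequence[np.ndarray],
                     ) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    """Resolve label switching across replicate runs and average the q
    matrices.

    Each run's clusters are permuted by exhaustive search over the k!
    permutations to maximize agreement with the first run (minimum Frobenius
    distance between q matrices, i.e. the full-search alignment criterion);
    exact for k=2.  Returns the aligned mean q and the permutation applied
    to each run.
    """
    qs = [r.q if isinstance(r, AdmixtureResults) else np.asarray(r) for r in runs]
    if not qs:
        raise ValueError("no runs supplied")
    k = qs[0].shape[1]
    if any(q.shape != qs[0].shape for q in qs):
        raise ValueError("all runs must share k and individuals")
    ref = qs[0]
    perms: list[tuple[int, ...]] = []
    total = np.zeros_like(ref)
    for q in qs:
        best, best_d = None, np.inf
        for perm in itertools.permutations(range(k)):
            d = float(((q[:, perm] - ref) ** 2).sum())
            if d < best_d:
                best, best_d = perm, d
        perms.append(best)
        total += q[:, best]
    return total / len(qs), perms


def evanno_delta_k(lnpd_by_k: dict[int, Sequence[float]],
                   reliability_threshold: float = 5.0) -> pd.DataFrame:
    """Evanno second-order rate-of-change statistic for choosing k.

    ``Delta k = mean(|L(k+1) - 2 L(k) + L(k-1)|) / sd(L(k))`` over replicate
    ln P(D) values; defined for interior k of a consecutive range with >= 3
    replicates each.  Cells with sd = 0 are flagged undefined.  The result
    frame carries ``chosen_k`` (argmax of Delta k) and ``reliable`` (False
    when every Delta k is below ``reliability_threshold``) as attributes
    ``.attrs["chosen_k"]`` / ``.attrs["reliable"]``.
    """
    ks = sorted(lnpd_by_k)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("k values must form a consecutive range")
    for k in ks:
        if len(lnpd_by_k[k]) < 3:
            raise ValueError(f"k={k}: need >= 3 replicates for the Evanno method")
    mean_l = {k: float(np.mean(lnpd_by_k[k])) for k in ks}
    sd_l = {k: float(np.std(lnpd_by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        row = {"k": k, "mean_lnpd": mean_l[k], "sd_lnpd": sd_l[k],
               "delta_k": np.nan, "undefined": False}
        if ks[0] < k < ks[-1]:
            reps = np.asarray(lnpd_by_k[k], dtype=float)
            lo = np.mean(lnpd_by_k[k - 1])
            hi = np.mean(lnpd_by_k[k + 1])
            second = np.abs(hi - 2 * reps + lo)
            if sd_l[k] == 0:
                row["undefined"] = True
            else:
                row["delta_k"] = float(np.mean(second) / sd_l[k])
        rows.append(row)
    df = pd.DataFrame(rows)
    finite = df["delta_k"].dropna()
    if finite.empty:
        df.attrs["chosen_k"] = None
        df.attrs["reliable"] = False
    else:
        df.attrs["chosen_k"] = int(df.loc[finite.idxmax(), "k"])
        df.attrs["reliable"] = bool(finite.max() >= reliability_threshold)
    return df


@dataclass
class AssignmentResult:
    """Discrete stock calls from an aligned mean q matrix."""

    q: np.ndarray
    labels: pd.Series          # per-individual label or "unassigned"
    q_threshold: float
    stock_names: tuple = ("stock_1", "stock_2")
    ties: list = field(default_factory=list)

    def counts(self) -> pd.Series:
        return self.labels.value_counts()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.q, index=self.labels.index,
                          columns=[f"q{c + 1}" for c in range(self.q.shape[1])])
        df["label"] = self.labels
        return df


def call_assignments(q: np.ndarray, individuals: Sequence[str] | None = None,
                     q_threshold: float = 0.8,
                     stock_names: Sequence[str] | None = None) -> AssignmentResult:
    """Label each individual with the cluster of its maximum q when that
    maximum reaches ``q_threshold``, else ``unassigned``.

    Exact ties at the maximum are broken toward the lower cluster index and
    recorded in ``result.ties``.
    """
    q = np.asarray(q, dtype=float)
    n, k = q.shape
    if stock_names is None:
        stock_names = tuple(f"stock_{c + 1}" for c in range(k))
    if individuals is None:
        individuals = [f"ind_{i}" for i in range(n)]
    best = np.argmax(q, axis=1)           # argmax breaks ties to lower index
    maxq = q[np.arange(n), best]
    ties = [individuals[i] for i in range(n)
            if (np.abs(q[i] - maxq[i]) < 1e-12).sum() > 1 and maxq[i] >= q_threshold]
    labels = pd.Series(
        [stock_names[b] if mq >= q_threshold else "unassigned"
         for b, mq in zip(best, maxq)],
        index=pd.Index(individuals, name="individual"), name="label")
    return AssignmentResult(q, labels, q_threshold, tuple(stock_names), ties)
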