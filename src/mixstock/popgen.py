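"""Per-locus and pairwise population-genetic statistics with resampling.

Implements the Weir & Cockerham (1984) variance-components estimator of the
fixation index (theta), observed/expected heterozygosity and F_IS,
permutation chi-square tests of Hardy-Weinberg equilibrium, bootstrap
confidence intervals, Holm sequential-Bonferroni correction, and the
bootstrap test for over/underrepresentation of the collinear allele at
inversion-linked loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PanelClass

__all__ = [
    "heterozygosities", "hwe_test", "hwe_chi2",
    "weir_cockerham_components", "fst_global", "fst_pairwise",
    "PairwiseFstMatrix", "temporal_pooling_test",
    "sequential_bonferroni", "collinear_allele_bootstrap",
]


# ---------------------------------------------------------------------------
# Heterozygosity and F_IS
# ---------------------------------------------------------------------------

def heterozygosities(g: GenotypeMatrix, grouping: str | None = None,
                     small_sample_correction: bool = False) -> pd.DataFrame:
    """Observed heterozygosity, Hardy-Weinberg expected heterozygosity and
    the inbreeding coefficient F_IS per (group, locus).

    H_obs is the fraction of heterozygous non-missing calls; H_exp is
    ``2 p (1-p)`` (optionally scaled by the unbiased-estimator factor
    ``2n/(2n-1)``); F_IS = 1 - H_obs/H_exp, NaN where H_exp = 0.
    """
    if grouping is None:
        codes, labels = np.zeros(g.n_individuals, dtype=int), ["all"]
    else:
        codes, labels = g.group_codes(grouping)
    rows = []
    for gi, label in enumerate(labels):
        sub = g.calls[codes == gi]
        ok = sub != MISSING
        n = ok.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ok, sub, 0).sum(axis=0) / (2.0 * n)
            h_obs = (sub == 1).sum(axis=0) / n
            h_exp = 2.0 * p * (1.0 - p)
            if small_sample_correction:
                h_exp = h_exp * np.where(n > 0.5, 2 * n / (2 * n - 1), np.nan)
            f_is = 1.0 - h_obs / h_exp
        for j, lid in enumerate(g.locus_ids):
            rows.append({"group": label, "locus": lid, "n": int(n[j]), "p": p[j],
                         "H_obs": h_obs[j], "H_exp": h_exp[j], "F_IS": f_is[j]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def hwe_chi2(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Chi-square of the three observed genotype classes against the
    Hardy-Weinberg expectation n*(q^2, 2pq, p^2) at the sample allele
    frequency.  NaN for monomorphic samples (an expectation is zero)."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return float("nan")
    p = (n_het + 2 * n_hom_alt) / (2.0 * n)
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    if (exp == 0).any():
        return float("nan")
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    return float(((obs - exp) ** 2 / exp).sum())


def _hwe_perm_one(calls: np.ndarray, n_perm: int, rng: np.random.Generator,
                  ) -> tuple[float, float]:
    """Permutation chi-square HWE test for one vector of non-missing calls.

    Permutation scheme: the group's 2n allele copies are randomly re-paired
    into diploids; p = (1 + #{chi2_perm >= chi2_obs}) / (n_perm + 1).
    """
    n = calls.size
    n_het = int((calls == 1).sum())
    n_alt = int((calls == 2).sum())
    chi2_obs = hwe_chi2(n - n_het - n_alt, n_het, n_alt)
    if not np.isfinite(chi2_obs):
        return chi2_obs, float("nan")
    n_alt_alleles = n_het + 2 * n_alt
    alleles = np.zeros((n_perm, 2 * n), dtype=np.int8)
    alleles[:, :n_alt_alleles] = 1
    rng.permuted(alleles, axis=1, out=alleles)
    pairs = alleles.reshape(n_perm, n, 2).sum(axis=2)
    k_het = (pairs == 1).sum(axis=1)
    k_alt = (pairs == 2).sum(axis=1)
    k_ref = n - k_het - k_alt
    # chi2 depends only on the genotype counts; allele freq is invariant
    p = n_alt_alleles / (2.0 * n)
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    chi2_perm = ((k_ref - exp[0]) ** 2 / exp[0]
                 + (k_het - exp[1]) ** 2 / exp[1]
                 + (k_alt - exp[2]) ** 2 / exp[2])
    p_perm = (1.0 + np.sum(chi2_perm >= chi2_obs - 1e-12)) / (n_perm + 1.0)
    return chi2_obs, float(p_perm)


def hwe_test(g: GenotypeMatrix, grouping: str | None = None, n_perm: int = 10_000,
             seed: int | np.random.Generator | None = None,
             include_pooled: bool = False) -> pd.DataFrame:
    """Permutation chi-square test of Hardy-Weinberg equilibrium per
    (group, locus); optionally also pooled over all groups.

    Monomorphic (group, locus) cells are flagged with NaN statistics.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if grouping is None:
        codes, labels = np.zeros(g.n_individuals, dtype=int), ["all"]
        include_pooled = False
    else:
        codes, labels = g.group_codes(grouping)
    groups: list[tuple[str, np.ndarray]] = [
        (label, g.calls[codes == gi]) for gi, label in enumerate(labels)]
    if include_pooled:
        groups.append(("pooled", g.calls))
    rows = []
    for label, sub in groups:
        for j, lid in enumerate(g.locus_ids):
            col = sub[:, j]
            col = col[col != MISSING]
            chi2, p = _hwe_perm_one(col, n_perm, rng) if col.size else (np.nan, np.nan)
            rows.append({"group": label, "locus": lid, "chi2": chi2, "p": p,
                         "tested": bool(np.isfinite(chi2))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------

def weir_cockerham_components(calls: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Per-locus Weir-Cockerham (1984) variance components for biallelic
    diploid data.

    Parameters
    ----------
    calls : (n_individuals, n_loci) int array
        Alt-allele counts with MISSING sentinel.
    codes : (n_individuals,) int array
        Population code per individual; negative codes are ignored.

    Returns
    -------
    (n_loci, 3) array of components (a, b, c): among populations, among
    individuals within populations, within individuals.  Rows are NaN where
    fewer than two populations have data or every population has a single
    individual (n_bar = 1).
    """
    calls = np.asarray(calls)
    codes = np.asarray(codes)
    pops = np.unique(codes[codes >= 0])
    n_loci = calls.shape[1]
    ok = (calls != MISSING) & (codes >= 0)[:, None]
    # per population x locus: sample size, allele freq, het fraction
    n_il = np.stack([(ok & (codes == k)[:, None]).sum(axis=0) for k in pops])
    with np.errstate(invalid="ignore", divide="ignore"):
        sum_alt = np.stack([
            np.where(ok & (codes == k)[:, None], calls, 0).sum(axis=0) for k in pops])
        p_il = sum_alt / (2.0 * n_il)
        h_il = np.stack([
            (np.where(ok, calls, MISSING)[codes == k] == 1).sum(axis=0) for k in pops
        ]) / n_il
    out = np.full((n_loci, 3), np.nan)
    for j in range(n_loci):
        use = n_il[:, j] > 0
        r = int(use.sum())
        if r < 2:
            continue
        n_i = n_il[use, j].astype(float)
        p_i = p_il[use, j]
        h_i = h_il[use, j]
        n_bar = n_i.mean()
        if n_bar <= 1:
            continue
        n_c = (r * n_bar - (n_i ** 2).sum() / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum() / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        out[j] = (a, b, c)
    return out


def _ratio_and_delta_se(comp: np.ndarray) -> tuple[float, float]:
    """Multi-locus theta (ratio of summed components) and its linearization
    standard error over loci: se = sqrt(m * var_j(a_j - theta * s_j)) / T
    with s_j the per-locus component sum and T their total."""
    m = comp.shape[0]
    a_sum, total = comp[:, 0].sum(), comp.sum()
    theta = a_sum / total
    if m < 2:
        return theta, 0.0
    resid = comp[:, 0] - theta * comp.sum(axis=1)
    return theta, float(np.sqrt(m * resid.var(ddof=1)) / total)


def _theta_from_components(comp: np.ndarray, multi_locus: bool) -> np.ndarray | float:
    with np.errstate(invalid="ignore", divide="ignore"):
        if multi_locus:
            s = np.nansum(comp, axis=0)
            if not np.isfinite(comp).any():
                return float("nan")
            return float(s[0] / s.sum()) if s.sum() != 0 else float("nan")
        return comp[:, 0] / comp.sum(axis=1)


def fst_global(g: GenotypeMatrix, grouping: str, n_boot: int = 10_000,
               seed: int | np.random.Generator | None = None,
               ci_level: float = 0.95) -> pd.DataFrame:
    """Per-locus Weir-Cockerham theta over the groups of ``grouping`` with a
    bootstrap percentile confidence interval.

    The CI resamples individuals with replacement within each group
    (stratified bootstrap), recomputing theta each replicate.  Negative theta
    estimates are reported as-is, not clipped at zero.
    """
    rng = np.random.default_rng(seed)
    codes, labels = g.group_codes(grouping)
    comp = weir_cockerham_components(g.calls, codes)
    theta = _theta_from_components(comp, multi_locus=False)
    boots = np.full((n_boot, g.n_loci), np.nan)
    group_rows = [np.flatnonzero(codes == gi) for gi in range(len(labels))]
    for b in range(n_boot):
        idx = np.concatenate([rows[rng.integers(0, rows.size, rows.size)]
                              for rows in group_rows if rows.size])
        bcomp = weir_cockerham_components(g.calls[idx], codes[idx])
        with np.errstate(invalid="ignore", divide="ignore"):
            boots[b] = bcomp[:, 0] / bcomp.sum(axis=1)
    alpha = 1.0 - ci_level
    with np.errstate(invalid="ignore"):
        lo = np.nanpercentile(boots, 100 * alpha / 2, axis=0) if n_boot else np.nan
        hi = np.nanpercentile(boots, 100 * (1 - alpha / 2), axis=0) if n_boot else np.nan
    return pd.DataFrame({
        "locus": g.locus_ids, "theta": theta,
        "ci_low": lo, "ci_high": hi,
        # differentiation is one-sided: a CI entirely below zero reflects the
        # estimator's negative bias under panmixia, not genetic structure
        "significant": np.asarray(lo) > 0,
        "ci_method": "bootstrap individuals within groups",
    })


@dataclass
class PairwiseFstMatrix:
    """Symmetric pairwise multi-locus theta with CIs and significance flags.

    A pair is flagged significant when the lower CI bound exceeds zero
    (evidence of differentiation); intervals entirely below zero are treated
    as no evidence, since negative theta estimates arise from sampling noise
    under panmixia.
    """

    labels: list[str]
    theta: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    significant: pd.DataFrame
    ci_method: str = "studentized bootstrap over loci"

    def to_table(self) -> pd.DataFrame:
        """Publication-style layout: theta below the diagonal, ``lo-hi``
        confidence intervals above."""
        k = len(self.labels)
        out = pd.DataFrame("", index=self.labels, columns=self.labels)
        for i in range(k):
            for j in range(k):
                if i > j:
                    out.iloc[i, j] = f"{self.theta.iloc[i, j]:.3f}"
                elif i < j:
                    out.iloc[i, j] = (f"{self.ci_low.iloc[i, j]:.2f}-"
                                      f"{self.ci_high.iloc[i, j]:.2f}")
        return out


def fst_pairwise(g: GenotypeMatrix, grouping: str, n_boot: int = 10_000,
                 seed: int | np.random.Generator | None = None,
                 ci_level: float = 0.95) -> PairwiseFstMatrix:
    """Multi-locus pairwise theta between every pair of groups.

    The multi-locus estimate is the ratio of variance components summed over
    loci (not the mean of per-locus ratios).  The CI is a studentized
    (bootstrap-t) interval over loci: resampled theta values are standardized
    by their own linearization standard error, which corrects the skew and
    small-panel narrowness of plain percentile intervals on ratio
    statistics.  Panels with a degenerate spread (e.g. all loci fixed
    different) report a point interval at the estimate.
    """
    rng = np.random.default_rng(seed)
    codes, labels = g.group_codes(grouping)
    k = len(labels)
    theta = np.zeros((k, k))
    lo = np.zeros((k, k))
    hi = np.zeros((k, k))
    sig = np.zeros((k, k), dtype=bool)
    alpha = 1.0 - ci_level
    for i in range(k):
        for j in range(i + 1, k):
            mask = (codes == i) | (codes == j)
            comp = weir_cockerham_components(g.calls[mask], codes[mask])
            t = _theta_from_components(comp, multi_locus=True)
            usable = np.flatnonzero(np.isfinite(comp).all(axis=1))
            comp_use = comp[usable]
            m = usable.size
            t_hat, se = _ratio_and_delta_se(comp_use) if m else (t, 0.0)
            if n_boot and m >= 2 and se > 0:
                picks = rng.integers(0, m, size=(n_boot, m))
                sums = comp_use[picks]                       # (B, m, 3)
                with np.errstate(invalid="ignore", divide="ignore"):
                    totals = sums.sum(axis=(1, 2))
                    tb = sums[..., 0].sum(axis=1) / totals
                    resid = sums[..., 0] - tb[:, None] * sums.sum(axis=2)
                    seb = np.sqrt(m * resid.var(axis=1, ddof=1)) / totals
                    tstar = (tb - t_hat) / seb
                tstar = tstar[np.isfinite(tstar)]
                q_lo, q_hi = np.percentile(
                    tstar, [100 * alpha / 2, 100 * (1 - alpha / 2)])
                l_, h_ = t_hat - q_hi * se, t_hat - q_lo * se
            else:
                l_ = h_ = t
            theta[i, j] = theta[j, i] = t
            lo[i, j] = lo[j, i] = l_
            hi[i, j] = hi[j, i] = h_
            sig[i, j] = sig[j, i] = l_ > 0  # one-sided, as for fst_global
    mk = lambda m: pd.DataFrame(m, index=labels, columns=labels)
    return PairwiseFstMatrix(labels, mk(theta), mk(lo), mk(hi), mk(sig))


def multilocus_theta(g: GenotypeMatrix, grouping: str) -> float:
    """Multi-locus Weir-Cockerham theta over all groups (components summed
    over loci before the ratio)."""
    codes, _ = g.group_codes(grouping)
    comp = weir_cockerham_components(g.calls, codes)
    return _theta_from_components(comp, multi_locus=True)


def temporal_pooling_test(g: GenotypeMatrix, unit: str,
                          grouping: str = "sampling_unit", year_key: str = "year",
                          n_boot: int = 10_000,
                          seed: int | np.random.Generator | None = None) -> dict:
    """Test whether year-strata of one sampling unit are genetically
    differentiated; recommend pooling iff no pair is significant.

    Returns a dict with the pairwise matrix over year strata, the maximum
    theta, and the pooling recommendation.
    """
    mask = (g.metadata[grouping] == unit).to_numpy()
    sub = g.subset(individuals=mask)
    years = sub.metadata[year_key]
    strata = sorted(years.dropna().unique().tolist())
    if len(strata) < 2:
        return {"unit": unit, "strata": strata, "pool": True,
                "max_theta": float("nan"), "matrix": None,
                "note": "fewer than two year strata; pooling trivially"}
    sub.metadata["_stratum"] = years.astype(str)
    pw = fst_pairwise(sub, "_stratum", n_boot=n_boot, seed=seed)
    any_sig = bool(pw.significant.to_numpy().any())
    vals = pw.theta.to_numpy()
    return {"unit": unit, "strata": strata, "pool": not any_sig,
            "max_theta": float(np.nanmax(vals)) if np.isfinite(vals).any() else float("nan"),
            "matrix": pw}


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def sequential_bonferroni(p_values, alpha: float = 0.05) -> pd.DataFrame:
    """Holm (1979) step-down sequential-Bonferroni correction.

    Sorted ascending, p_(i) is compared with alpha/(m-i+1); rejection stops
    at the first failure.  The adjusted p-value is the running maximum of
    (m-i+1)*p_(i), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    reject = np.zeros(m, dtype=bool)
    running = 0.0
    still_rejecting = True
    for rank, idx in enumerate(order):
        mult = m - rank
        running = max(running, min(1.0, mult * p[idx]))
        adj[idx] = running
        if still_rejecting and p[idx] <= alpha / mult:
            reject[idx] = True
        else:
            still_rejecting = False
    return pd.DataFrame({"p": p, "p_adjusted": adj, "reject": reject})


# ---------------------------------------------------------------------------
# Collinear-allele representation at inversion loci
# ---------------------------------------------------------------------------

def collinear_allele_bootstrap(g: GenotypeMatrix, grouping: str,
                               loci: list[str] | None = None,
                               n_boot: int = 10_000,
                               seed: int | np.random.Generator | None = None,
                               null_freq: float = 0.5,
                               alpha: float = 0.05) -> pd.DataFrame:
    """Bootstrap test of over/underrepresentation of the presumed collinear
    allele at inversion-linked loci, per group.

    Individuals are resampled with replacement within each group; the
    collinear-allele frequency is recomputed per replicate.  A cell is
    significant when the central bootstrap percentile interval excludes
    ``null_freq`` and the Holm-adjusted two-sided bootstrap p-value is below
    ``alpha``.  Groups with a single individual are flagged low-confidence.
    """
    rng = np.random.default_rng(seed)
    if loci is None:
        loci = [l.locus_id for l in g.loci if l.panel_class is PanelClass.INVERSION]
    lut = {l.locus_id: l for l in g.loci}
    for lid in loci:
        if lut[lid].collinear_allele is None:
            raise ValueError(f"{lid}: no collinear allele designated")
    codes, labels = g.group_codes(grouping)
    rows = []
    for gi, label in enumerate(labels):
        idx = np.flatnonzero(codes == gi)
        for lid in loci:
            j = g.locus_ids.index(lid)
            col = g.calls[idx, j]
            obs = col[col != MISSING]
            if obs.size == 0:
                rows.append({"group": label, "locus": lid, "collinear_freq": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "p_boot": np.nan,
                             "low_confidence": True})
                continue
            # frequency of the collinear arrangement
            def cfreq(v):
                p_alt = v.mean() / 2.0
                return p_alt if lut[lid].collinear_allele == "alt" else 1.0 - p_alt
            est = cfreq(obs)
            picks = obs[rng.integers(0, obs.size, size=(n_boot, obs.size))]
            p_alt_b = picks.mean(axis=1) / 2.0
            fb = p_alt_b if lut[lid].collinear_allele == "alt" else 1.0 - p_alt_b
            lo, hi = np.percentile(fb, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            # two-sided bootstrap p for H0: freq == null_freq
            p_one = (1.0 + min((fb <= null_freq).sum(), (fb >= null_freq).sum())) / (n_boot + 1.0)
            rows.append({"group": label, "locus": lid, "collinear_freq": est,
                         "ci_low": lo, "ci_high": hi,
                         "p_boot": min(1.0, 2.0 * p_one),
                         "low_confidence": obs.size < 2})
    df = pd.DataFrame(rows)
    tested = df["p_boot"].notna()
    df["significant"] = False
    if tested.any():
        holm = sequential_bonferroni(df.loc[tested, "p_boot"].to_numpy(), alpha=alpha)
        excl = (df.loc[tested, "ci_low"] > null_freq) | (df.loc[tested, "ci_high"] < null_freq)
        df.loc[tested, "significant"] = holm["reject"].to_numpy() & excl.to_numpy()
        df.loc[tested, "p_adjusted"] = holm["p_adjusted"].to_numpy()
    return df
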