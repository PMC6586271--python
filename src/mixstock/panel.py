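"""Diagnostic SNP panel selection under genome-architecture constraints.

Candidates are ranked by pairwise Weir-Cockerham theta between the two
reference populations; selection is greedy from the top of the ranking,
skipping candidates physically linked to an already selected locus (same
linkage group within ``min_spacing_bp``) or falling in a supplied exclusion
interval (e.g. a chromosomal inversion).  Assignment power of the resulting
panel is quantified by likelihood reassignment of holdout individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, LocusInfo
from .popgen import weir_cockerham_components


def rank_candidates(g: GenotypeMatrix, pop_a: str, pop_b: str,
                    grouping: str = "sampling_unit") -> pd.DataFrame:
    """Rank every locus by its pairwise theta between two reference groups.

    Returns a DataFrame sorted by descending score with ties broken by
    (linkage_group, position); NaN scores (unusable loci) sort last.
    """
    codes, labels = g.group_codes(grouping)
    for pop in (pop_a, pop_b):
        if pop not in labels:
            raise ValueError(f"group {pop!r} not found in {grouping!r}")
    sel = np.where(codes == labels.index(pop_a), 0,
                   np.where(codes == labels.index(pop_b), 1, -1))
    comp = weir_cockerham_components(g.calls, sel)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = comp[:, 0] / comp.sum(axis=1)
    df = pd.DataFrame({
        "locus": g.locus_ids,
        "linkage_group": [l.linkage_group for l in g.loci],
        "position_bp": [l.position_bp for l in g.loci],
        "score": theta,
    })
    df["_nan"] = ~np.isfinite(theta)
    df = df.sort_values(["_nan", "score", "linkage_group", "position_bp"],
                        ascending=[True, False, True, True], kind="stable")
    return df.drop(columns="_nan").reset_index(drop=True)


@dataclass
class PanelDesign:
    """Outcome of greedy constrained panel selection."""

    selected: list[LocusInfo]
    scores: dict[str, float]
    constraints_log: pd.DataFrame
    panel_size: int
    min_spacing_bp: int
    exclusion_intervals: pd.DataFrame | None
    warnings: list[str] = field(default_factory=list)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.selected]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus": self.locus_ids,
            "linkage_group": [l.linkage_group for l in self.selected],
            "position_bp": [l.position_bp for l in self.selected],
            "score": [self.scores[l.locus_id] for l in self.selected],
        })


def _in_exclusion(loc: LocusInfo, intervals: pd.DataFrame | None) -> bool:
    if intervals is None or intervals.empty:
        return False
    # BED half-open [start, end) on 0-based coordinates; positions are 1-based
    pos0 = loc.position_bp - 1
    hit = ((intervals["linkage_group"] == loc.linkage_group)
           & (intervals["start"] <= pos0) & (pos0 < intervals["end"]))
    return bool(hit.any())


def select_panel(ranked: pd.DataFrame, g: GenotypeMatrix, panel_size: int = 20,
                 min_spacing_bp: int = 1_000_000,
                 exclusion_intervals: pd.DataFrame | None = None) -> PanelDesign:
    """Greedy top-down selection of ``panel_size`` loci from a ranking.

    A candidate is rejected when it sits within ``min_spacing_bp`` of an
    already selected locus on the same linkage group (``rejected: linked``)
    or inside an exclusion interval (``rejected: excluded-region``); once the
    panel is full, remaining candidates log ``rejected: low-score``.  If the
    constraints leave fewer than ``panel_size`` survivors, the maximum
    feasible set is returned with a warning.
    """
    if panel_size < 1:
        raise ValueError("panel_size must be >= 1")
    lut = {l.locus_id: l for l in g.loci}
    selected: list[LocusInfo] = []
    log_rows = []
    warnings = []
    if ranked.empty:
        warnings.append("no candidates supplied; empty panel")
    for _, row in ranked.iterrows():
        loc = lut[row["locus"]]
        if len(selected) >= panel_size:
            decision = "rejected: low-score"
        elif not np.isfinite(row["score"]):
            decision = "rejected: low-score"
        elif _in_exclusion(loc, exclusion_intervals):
            decision = "rejected: excluded-region"
        elif any(s.linkage_group == loc.linkage_group
                 and abs(s.position_bp - loc.position_bp) < min_spacing_bp
                 for s in selected):
            decision = "rejected: linked"
        else:
            decision = "selected"
            selected.append(loc)
        log_rows.append({"locus": loc.locus_id, "decision": decision,
                         "score": row["score"]})
    if len(selected) < panel_size:
        warnings.append(
            f"only {len(selected)} of {panel_size} requested loci satisfy the "
            "constraints; returning the maximum feasible set")
    scores = dict(zip(ranked["locus"], ranked["score"]))
    return PanelDesign(selected, scores,
                       pd.DataFrame(log_rows, columns=["locus", "decision", "score"]),
                       panel_size, min_spacing_bp, exclusion_intervals, warnings)


# ---------------------------------------------------------------------------
# Assignment power
# ---------------------------------------------------------------------------

def _smoothed_freqs(calls: np.ndarray) -> np.ndarray:
    """Pseudocount-smoothed alt-allele frequency p' = (x + 0.5) / (2n + 1)
    per locus; avoids zero-probability genotypes in the likelihood."""
    ok = calls != MISSING
    x = np.where(ok, calls, 0).sum(axis=0)
    n = ok.sum(axis=0)
    return (x + 0.5) / (2.0 * n + 1.0)


def genotype_log_likelihood(calls: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Log-likelihood of each individual's multilocus genotype under
    Hardy-Weinberg proportions at frequencies ``p``; missing loci contribute
    nothing.  Rannala-Mountain style product over loci."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    calls = np.atleast_2d(calls)
    ll_het = np.log(2) + np.log(p) + np.log1p(-p)
    ll = np.where(calls == 0, 2 * np.log1p(-p),
                  np.where(calls == 1, ll_het, 2 * np.log(p)))
    return np.where(calls != MISSING, ll, 0.0).sum(axis=1)


def assign_by_likelihood(g: GenotypeMatrix, reference_groups: list[str],
                         grouping: str = "sampling_unit",
                         holdout_mask: np.ndarray | None = None,
                         leave_one_out: bool = True) -> pd.DataFrame:
    """Assign individuals to the reference group maximizing their genotype
    likelihood under that group's (smoothed) allele frequencies.

    Reference individuals are scored leave-one-out: their own genotype is
    removed from the frequency estimate of their source group before
    computing the likelihood.  Exact likelihood ties are labelled
    ``ambiguous``.
    """
    codes, labels = g.group_codes(grouping)
    ref_idx = {r: np.flatnonzero(codes == labels.index(r)) for r in reference_groups}
    rows_iter = (np.flatnonzero(holdout_mask) if holdout_mask is not None
                 else np.arange(g.n_individuals))
    base_freqs = {r: _smoothed_freqs(g.calls[idx]) for r, idx in ref_idx.items()}
    records = []
    for i in rows_iter:
        lls = {}
        for r, idx in ref_idx.items():
            if leave_one_out and i in idx:
                p = _smoothed_freqs(g.calls[idx[idx != i]])
            else:
                p = base_freqs[r]
            lls[r] = float(genotype_log_likelihood(g.calls[i:i + 1], p)[0])
        best = max(lls, key=lls.get)
        ties = [r for r in lls if abs(lls[r] - lls[best]) < 1e-9]
        records.append({"individual": g.individuals[i],
                        "assigned": "ambiguous" if len(ties) > 1 else best,
                        **{f"ll_{r}": lls[r] for r in reference_groups}})
    return pd.DataFrame(records)


def power_analysis(g: GenotypeMatrix, panel: PanelDesign | list[str],
                   reference_groups: list[str], holdout_groups: list[str],
                   grouping: str = "sampling_unit", n_replicates: int = 5,
                   holdout_fraction: float = 0.5,
                   seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Reassignment power of a panel: per replicate, a random half of each
    holdout group is assigned to the reference group maximizing its genotype
    likelihood; reference members of a holdout group are scored leave-one-out.

    Returns one row per (replicate, holdout group, reference group) with the
    fraction of holdout individuals assigned there, plus ``ambiguous``.
    """
    rng = np.random.default_rng(seed)
    locus_ids = panel.locus_ids if isinstance(panel, PanelDesign) else list(panel)
    sub = g.subset(loci=locus_ids)
    codes, labels = sub.group_codes(grouping)
    records = []
    for rep in range(n_replicates):
        for hg in holdout_groups:
            members = np.flatnonzero(codes == labels.index(hg))
            take = max(1, int(round(holdout_fraction * members.size)))
            chosen = rng.choice(members, size=take, replace=False)
            mask = np.zeros(sub.n_individuals, dtype=bool)
            mask[chosen] = True
            res = assign_by_likelihood(sub, reference_groups, grouping,
                                       holdout_mask=mask)
            counts = res["assigned"].value_counts(normalize=True)
            for r in list(reference_groups) + ["ambiguous"]:
                records.append({"replicate": rep, "holdout": hg, "reference": r,
                                "fraction_assigned": float(counts.get(r, 0.0)),
                                "n_holdout": take})
    df = pd.DataFrame(records)
    return df


def power_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of the assigned fraction over replicates, per
    (holdout, reference) cell."""
    return (report.groupby(["holdout", "reference"])["fraction_assigned"]
            .agg(["mean", "std"]).reset_index())
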