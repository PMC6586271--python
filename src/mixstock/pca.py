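"""Reference-anchored PCA assignment with Tracy-Widom significance.

The eigenvectors are inferred from reference individuals only (the axes of
variation between the known source populations); every other individual is
placed on those axes by least-squares projection of its observed genotypes,
so missing data do not drag projected points toward the origin.  Eigenvalue
significance follows the Patterson moment-matching construction against the
Tracy-Widom (beta=1) null for the largest eigenvalue of a Wishart matrix.

statsmodels-style surface: ``ReferencePCA(g, reference=...).fit()`` returns a
:class:`PCAResults` carrying coordinates, eigenvalues, Tracy-Widom tests and
the nearest-centroid assignment rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._tw_table import TW1_CDF, TW1_X
from .io import MISSING, GenotypeMatrix

__all__ = ["ReferencePCA", "PCAResults", "tracy_widom_test", "tw_sf"]

P_FLOOR = 1e-6


def tw_sf(x) -> np.ndarray:
    """Upper-tail probability of the Tracy-Widom (beta=1) distribution by
    linear interpolation of the bundled quantile table.

    Statistics below the table range report p = 1.0 exactly (the convention
    used when printing non-significant axes); above the range the p-value is
    floored at 1e-6.
    """
    x = np.asarray(x, dtype=float)
    sf = 1.0 - np.interp(x, TW1_X, TW1_CDF)
    sf = np.where(x < TW1_X[0], 1.0, np.where(x > TW1_X[-1], P_FLOOR, sf))
    return np.clip(sf, P_FLOOR, 1.0)


def tracy_widom_test(eigenvalues: np.ndarray) -> pd.DataFrame:
    """Patterson-style sequential Tracy-Widom tests of PCA eigenvalues.

    For each axis the leading axes are removed and the remaining eigenvalues
    are moment-matched to a Wishart null: the effective number of markers is
    ``n' = (m+1)(sum l)^2 / ((m-1) sum l^2 - (sum l)^2)`` with ``m`` the
    number of remaining eigenvalues; the leading remaining eigenvalue is
    standardized with the Tracy-Widom centering and scaling constants and
    referred to the TW1 distribution.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 1e-12]
    rows = []
    for axis in range(lam.size):
        rest = lam[axis:]
        m = rest.size
        if m < 2:
            rows.append({"axis": axis + 1, "twstat": np.nan, "p": np.nan})
            continue
        s1, s2 = rest.sum(), (rest ** 2).sum()
        denom = (m - 1) * s2 - s1 ** 2
        if denom <= 0:
            rows.append({"axis": axis + 1, "twstat": np.nan, "p": np.nan})
            continue
        n_eff = (m + 1) * s1 ** 2 / denom
        if n_eff <= 1:
            rows.append({"axis": axis + 1, "twstat": np.nan, "p": np.nan})
            continue
        l_norm = m * rest[0] / s1
        sq_n = np.sqrt(n_eff - 1)
        sq_m = np.sqrt(m)
        mu = (sq_n + sq_m) ** 2 / n_eff
        sigma = (sq_n + sq_m) / n_eff * (1.0 / sq_n + 1.0 / sq_m) ** (1.0 / 3.0)
        tw = (l_norm - mu) / sigma
        rows.append({"axis": axis + 1, "twstat": float(tw), "p": float(tw_sf(tw))})
    return pd.DataFrame(rows)


class ReferencePCA:
    """PCA of normalized genotypes anchored on reference individuals.

    Parameters
    ----------
    g : GenotypeMatrix
        All individuals (references and those to be projected).
    reference : sequence of str or boolean mask
        The individuals used to estimate locus frequencies and eigenvectors.
    """

    def __init__(self, g: GenotypeMatrix, reference):
        self.g = g
        mask = np.zeros(g.n_individuals, dtype=bool)
        if isinstance(reference, np.ndarray) and reference.dtype == bool:
            mask = reference.copy()
        else:
            pos = {ind: i for i, ind in enumerate(g.individuals)}
            for ind in reference:
                mask[pos[ind]] = True
        if mask.sum() < 2:
            raise ValueError("need at least two reference individuals")
        self.reference_mask = mask

    def normalized(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Normalized genotype matrix for all individuals plus the reference
        posterior frequencies and the per-locus scale.

        Per locus, the posterior alt-allele frequency over reference
        individuals is ``p = (1 + sum calls) / (2 + 2 n_nonmissing)``; each
        entry becomes ``(call - 2p)/sqrt(p(1-p))`` and missing entries are 0
        after centering.
        """
        calls = self.g.calls
        ref = calls[self.reference_mask]
        ok_ref = ref != MISSING
        n = ok_ref.sum(axis=0)
        p = (1.0 + np.where(ok_ref, ref, 0).sum(axis=0)) / (2.0 + 2.0 * n)
        scale = np.sqrt(p * (1.0 - p))
        ok = calls != MISSING
        x = np.where(ok, (calls - 2.0 * p) / scale, 0.0)
        return x, p, scale

    def fit(self, n_axes: int | None = None) -> "PCAResults":
        """Eigendecomposition of the reference individual covariance and
        least-squares projection of every non-reference individual."""
        x, p, scale = self.normalized()
        ref_rows = np.flatnonzero(self.reference_mask)
        x_ref = x[ref_rows]
        n_ref, L = x_ref.shape
        ref_calls = self.g.calls[self.reference_mask]
        ok_ref = ref_calls != MISSING
        col_min = np.where(ok_ref, ref_calls, 3).min(axis=0)
        col_max = np.where(ok_ref, ref_calls, -2).max(axis=0)
        if not (col_max > col_min).any():
            raise ValueError("no polymorphic locus among the references")
        # SVD of the reference matrix: eigenvalues of X X^T / L are s^2 / L
        u, s, vt = np.linalg.svd(x_ref, full_matrices=False)
        eigvals = s ** 2 / L
        max_axes = int((eigvals > 1e-12).sum())
        if n_axes is None:
            n_axes = max_axes
        n_axes = min(n_axes, max_axes)
        loadings = vt[:n_axes].T                     # (L, n_axes), orthonormal
        ref_coords = u[:, :n_axes] * s[:n_axes]
        coords = np.full((self.g.n_individuals, n_axes), np.nan)
        coords[ref_rows] = ref_coords
        ok = self.g.calls != MISSING
        for i in np.flatnonzero(~self.reference_mask):
            o = ok[i]
            if not o.any():
                continue  # flagged by the NaN row
            sol, *_ = np.linalg.lstsq(loadings[o], x[i, o], rcond=None)
            coords[i] = sol
        var_explained = eigvals[:n_axes] / eigvals.sum()
        return PCAResults(self, eigvals[:n_axes], var_explained, coords,
                          loadings, p)


@dataclass
class PCAResults:
    """Coordinates, eigenvalues and significance tests of a reference PCA."""

    model: ReferencePCA
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    coords: np.ndarray            # (n_individuals, n_axes); NaN = unprojectable
    loadings: np.ndarray          # (L, n_axes)
    ref_freqs: np.ndarray

    def coords_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords, index=self.model.g.individuals,
                          columns=[f"PC{a + 1}" for a in range(self.coords.shape[1])])
        df.index.name = "individual"
        df["reference"] = self.model.reference_mask
        return df

    def project(self, calls: np.ndarray) -> np.ndarray:
        """Least-squares coordinates for new individuals genotyped at the
        fitted loci (rows of alt-allele counts with the MISSING sentinel)."""
        calls = np.atleast_2d(calls)
        _, p, scale = self.model.normalized()
        out = np.full((calls.shape[0], self.loadings.shape[1]), np.nan)
        for i, row in enumerate(calls):
            o = row != MISSING
            if not o.any():
                continue
            x = (row[o] - 2.0 * p[o]) / scale[o]
            out[i], *_ = np.linalg.lstsq(self.loadings[o], x, rcond=None)
        return out

    def tracy_widom(self) -> pd.DataFrame:
        return tracy_widom_test(self.eigenvalues)

    def significant_axes(self, alpha: float = 0.01) -> list[int]:
        """Leading consecutive run of Tracy-Widom-significant axes (testing
        stops at the first non-significant axis); falls back to axis 1 when
        none is significant."""
        tw = self.tracy_widom()
        axes: list[int] = []
        for _, row in tw.iterrows():
            if np.isfinite(row["p"]) and row["p"] < alpha:
                axes.append(int(row["axis"]))
            else:
                break
        return axes or [1]

    def assign(self, reference_labels: pd.Series | dict,
               axes: list[int] | None = None,
               margin: float = 0.2, alpha: float = 0.01) -> pd.DataFrame:
        """Nearest-centroid stock assignment on the significant axes.

        Reference-cluster centroids are computed from the labelled reference
        individuals; each individual is assigned to the nearest centroid
        unless the relative distance margin ``(d2 - d1) / d2`` between the
        two nearest centroids falls below ``margin`` (then ``unassigned``).
        """
        if axes is None:
            axes = self.significant_axes(alpha)
        cols = [a - 1 for a in axes]
        labels = pd.Series(reference_labels)
        g = self.model.g
        pos = {ind: i for i, ind in enumerate(g.individuals)}
        centroids = {}
        for lab in sorted(labels.unique()):
            rows = [pos[ind] for ind in labels.index[labels == lab]]
            centroids[lab] = np.nanmean(self.coords[np.ix_(rows, cols)], axis=0)
        names = list(centroids)
        records = []
        for i, ind in enumerate(g.individuals):
            c = self.coords[i, cols]
            if not np.isfinite(c).all():
                records.append({"individual": ind, "label": "unassigned",
                                "margin": np.nan})
                continue
            d = np.array([np.linalg.norm(c - centroids[nm]) for nm in names])
            order = np.argsort(d)
            d1, d2 = d[order[0]], d[order[1]] if len(d) > 1 else np.inf
            rel = (d2 - d1) / d2 if d2 > 0 else 0.0
            records.append({
                "individual": ind,
                "label": names[order[0]] if rel >= margin else "unassigned",
                "margin": rel})
        return pd.DataFrame(records).set_index("individual")

    def summary(self) -> str:
        tw = self.tracy_widom()
        lines = [f"Reference PCA: {int(self.model.reference_mask.sum())} reference "
                 f"individuals, {self.loadings.shape[0]} loci"]
        for _, r in tw.head(4).iterrows():
            ve = self.variance_explained[int(r['axis']) - 1]
            pstr = "nan" if not np.isfinite(r["p"]) else (
                "<0.01" if r["p"] < 0.01 else f"{r['p']:.2f}")
            lines.append(f"  axis {int(r['axis'])}: eigenvalue "
                         f"{self.eigenvalues[int(r['axis']) - 1]:.3f}, "
                         f"{100 * ve:.2f}% variance, TW {r['twstat']:.3f}, p {pstr}")
        return "\n".join(lines)

    def plot(self, ax=None, color_by: str | None = "sampling_unit"):
        """Scatter of the first two axes, coloured by a metadata column."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        meta = self.model.g.metadata
        groups = (meta[color_by] if color_by in meta.columns
                  else pd.Series("all", index=meta.index))
        for lab in sorted(groups.dropna().unique()):
            rows = np.flatnonzero((groups == lab).to_numpy())
            ax.scatter(self.coords[rows, 0],
                       self.coords[rows, 1] if self.coords.shape[1] > 1
                       else np.zeros(rows.size),
                       s=12, label=str(lab))
        ax.set_xlabel(f"PC1 ({100 * self.variance_explained[0]:.1f}%)")
        if self.coords.shape[1] > 1:
            ax.set_ylabel(f"PC2 ({100 * self.variance_explained[1]:.1f}%)")
        ax.legend(fontsize="small")
        return ax
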