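"""Migration profiles and per-protein differential statistics.

A protein's *migration profile* is its per-slice intensity vector along the
BN-PAGE lane.  Group profiles average the normalized profiles of a group's
biological replicates (zeros count as measured values).  Two statistics are
computed per protein between two groups:

* a Welch two-sample t-test on the per-replicate totals over all S slices
  (does overall abundance differ?), and
* an amplitude-adjusted Euclidean distance between the group-mean profiles,
  ``d = ||a - b||_2 / max(max a, max b)`` (does the migration *shape*
  differ, independent of overall abundance?).

The :class:`DifferentialAbundanceModel` / :class:`DifferentialAbundanceResults`
pair wraps these per-protein statistics over a whole matrix with a summary
table, in the style of statsmodels model objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .core import ComplexomeMatrix

__all__ = [
    "GroupProfile",
    "DifferentialResult",
    "group_mean_profile",
    "max_scale",
    "detection_count",
    "welch_from_sums",
    "welch_total_abundance_test",
    "amplitude_adjusted_distance",
    "cluster_order",
    "DifferentialAbundanceModel",
    "DifferentialAbundanceResults",
]


@dataclass
class GroupProfile:
    """Replicate-averaged per-slice profile of one protein in one group."""

    protein: str
    group: str
    mean: np.ndarray  # length S
    sd: np.ndarray    # length S, n-1 sample SD (0 when n == 1)
    n_replicates: int


def group_mean_profile(matrix: ComplexomeMatrix, group: str, protein: str) -> GroupProfile:
    """Mean and SD across a group's replicates, per slice.

    Zeros are ordinary measured values; the SD uses the n-1 convention and
    is 0 for a single replicate.
    """
    vals = matrix.group_values(protein, group)  # (S, n)
    n = vals.shape[1]
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1) if n > 1 else np.zeros(vals.shape[0])
    return GroupProfile(protein=protein, group=group, mean=mean, sd=sd, n_replicates=n)


def max_scale(profile: np.ndarray) -> np.ndarray:
    """Scale a nonnegative vector so its peak is exactly 1.

    All-zero input is returned unchanged (as a copy).  This is the per-row
    scaling used for migration heat maps, where each protein is normalized
    to its gel slice with highest intensity.
    """
    profile = np.asarray(profile, dtype=float)
    m = profile.max() if profile.size else 0.0
    if m <= 0:
        return profile.copy()
    return profile / m


def detection_count(matrix: ComplexomeMatrix, group: str, protein: str) -> int:
    """Number of the group's replicates in which the protein was detected
    (summed intensity over all slices > 0)."""
    vals = matrix.group_values(protein, group)
    return int(np.count_nonzero(vals.sum(axis=0) > 0))


def welch_from_sums(sums_a: np.ndarray, sums_b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test on two small samples.

    Returns ``(t, df, p)`` with the Welch statistic
    ``t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b)``, the
    Welch-Satterthwaite degrees of freedom, and the two-sided p-value from
    the t distribution.  Degenerate cases: both variances zero with equal
    means -> (0, n_a+n_b-2, 1); with unequal means -> (+-inf, ..., 0).
    """
    a = np.asarray(sums_a, dtype=float)
    b = np.asarray(sums_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("Welch test needs at least 2 replicates per group")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        df = float(na + nb - 2)
        if ma == mb:
            return 0.0, df, 1.0
        return float(np.sign(ma - mb)) * np.inf, df, 0.0
    t = (ma - mb) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_total_abundance_test(
    matrix: ComplexomeMatrix, protein: str, group_a: str, group_b: str,
) -> "DifferentialResult":
    """Welch test of a protein's per-replicate slice-sum totals, group a vs b.

    Each replicate contributes one number: the sum of its S normalized slice
    intensities.  Swapping groups negates t and preserves p.  The distance
    field is filled when both group-mean profiles are not all-zero,
    otherwise left as NaN.
    """
    vals_a = matrix.group_values(protein, group_a)
    vals_b = matrix.group_values(protein, group_b)
    sums_a = vals_a.sum(axis=0)
    sums_b = vals_b.sum(axis=0)
    t, df, p = welch_from_sums(sums_a, sums_b)
    mean_a, mean_b = vals_a.mean(axis=1), vals_b.mean(axis=1)
    if mean_a.max() > 0 or mean_b.max() > 0:
        d = amplitude_adjusted_distance(mean_a, mean_b)
    else:
        d = float("nan")
    return DifferentialResult(protein=protein, sums_a=sums_a, sums_b=sums_b,
                              welch_t=t, welch_df=df, p_value=p, distance=d)


@dataclass
class DifferentialResult:
    """Per-protein differential statistics between two groups."""

    protein: str
    sums_a: np.ndarray
    sums_b: np.ndarray
    welch_t: float
    welch_df: float
    p_value: float
    distance: float


def amplitude_adjusted_distance(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Euclidean distance between two profiles divided by their maximal value.

    The division by ``max(max a, max b)`` removes amplitude-introduced bias:
    the result is invariant under common positive rescaling of both
    profiles, zero iff they are identical, and symmetric.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    denom = max(a.max(), b.max())
    if denom <= 0:
        raise ValueError("amplitude-adjusted distance undefined for two all-zero profiles")
    return float(np.linalg.norm(a - b) / denom)


def cluster_order(profiles: pd.DataFrame | np.ndarray,
                  proteins: list[str] | None = None) -> list[str]:
    """Order proteins by agglomerative clustering of max-scaled profiles.

    Average linkage, Euclidean metric; the leaf order of the dendrogram is
    returned.  Ties (identical profiles) are broken by input order, which
    scipy's deterministic linkage preserves.  Accepts a DataFrame (index =
    protein ids) or an array plus an explicit id list.
    """
    if isinstance(profiles, pd.DataFrame):
        proteins = list(profiles.index)
        mat = profiles.to_numpy(dtype=float)
    else:
        mat = np.asarray(profiles, dtype=float)
        if proteins is None:
            raise ValueError("protein ids required with an array input")
        proteins = list(proteins)
    if len(proteins) == 0:
        raise ValueError("at least one profile required")
    if len(proteins) == 1:
        return proteins
    scaled = np.vstack([max_scale(row) for row in mat])
    lk = linkage(scaled, method="average", metric="euclidean")
    return [proteins[i] for i in leaves_list(lk)]


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class DifferentialAbundanceModel:
    """Per-protein differential model between a reference and a test group.

    For every protein the model computes the Welch t-test on per-replicate
    slice-sum totals and the amplitude-adjusted Euclidean distance between
    the two group-mean migration profiles.

    Parameters
    ----------
    matrix
        Normalized, proteotypic-filtered complexome matrix.
    group_a, group_b
        Reference (e.g. ``"WT"``) and test (e.g. ``"lpa2"``) group labels.
    """

    def __init__(self, matrix: ComplexomeMatrix, group_a: str, group_b: str):
        if group_a not in matrix.design.groups or group_b not in matrix.design.groups:
            raise KeyError(f"groups {group_a!r}/{group_b!r} not both in design "
                           f"{matrix.design.groups}")
        self.matrix = matrix
        self.group_a = group_a
        self.group_b = group_b

    @classmethod
    def from_files(cls, intensity_path, annotation_path, group_a: str, group_b: str,
                   proteotypic_filter: bool = True) -> "DifferentialAbundanceModel":
        """Build the model from TSV files: read, normalize, filter."""
        from .io import read_annotations, read_intensity_table
        from .normalize import filter_proteotypic, normalize

        matrix = read_intensity_table(intensity_path)
        ann = read_annotations(annotation_path)
        norm = normalize(matrix)
        filtered = (filter_proteotypic(norm.normalized, ann)
                    if proteotypic_filter else norm.normalized)
        return cls(filtered, group_a, group_b)

    def fit(self) -> "DifferentialAbundanceResults":
        """Compute the per-protein statistics for every protein."""
        results = [welch_total_abundance_test(self.matrix, p, self.group_a, self.group_b)
                   for p in self.matrix.proteins]
        return DifferentialAbundanceResults(self, results)


class DifferentialAbundanceResults:
    """Fitted per-protein statistics with a tabular view and summary."""

    def __init__(self, model: DifferentialAbundanceModel,
                 results: list[DifferentialResult]):
        self.model = model
        self.results = results
        rows = []
        for r in results:
            rows.append({
                "protein": r.protein,
                "total_a": float(np.sum(r.sums_a)),
                "total_b": float(np.sum(r.sums_b)),
                "welch_t": r.welch_t,
                "welch_df": r.welch_df,
                "p_value": r.p_value,
                "distance": r.distance,
            })
        frame = pd.DataFrame(rows).set_index("protein")
        # Benjamini-Hochberg column: an extension beyond the raw p-values,
        # provided for convenience and clearly labeled as adjusted.
        finite = np.isfinite(frame["p_value"].to_numpy())
        adj = np.full(len(frame), np.nan)
        if finite.any():
            adj[finite] = stats.false_discovery_control(
                frame["p_value"].to_numpy()[finite], method="bh")
        frame["p_adj_bh"] = adj
        self.frame = frame

    def __getitem__(self, protein: str) -> DifferentialResult:
        for r in self.results:
            if r.protein == protein:
                return r
        raise KeyError(protein)

    def group_profile(self, protein: str, group: str) -> GroupProfile:
        return group_mean_profile(self.model.matrix, group, protein)

    def profiles_frame(self) -> pd.DataFrame:
        """Long-format group profiles: protein, group, slice, mean, sd."""
        rows = []
        for protein in self.model.matrix.proteins:
            for group in (self.model.group_a, self.model.group_b):
                gp = group_mean_profile(self.model.matrix, group, protein)
                for k in range(self.model.matrix.n_slices):
                    rows.append({"protein": protein, "group": group, "slice": k + 1,
                                 "mean": gp.mean[k], "sd": gp.sd[k]})
        return pd.DataFrame(rows)

    def summary(self, alpha: float = 0.05, top: int = 10) -> str:
        """Human-readable synopsis: counts and the most changed proteins."""
        f = self.frame
        n = len(f)
        n_sig = int((f["p_value"] < alpha).sum())
        lines = [
            "Differential abundance (Welch test on slice-sum totals)",
            "=" * 58,
            f"groups:            {self.model.group_a} (reference) vs {self.model.group_b}",
            f"proteins tested:   {n}",
            f"p < {alpha:<4g}:         {n_sig}",
            f"median distance:   {np.nanmedian(f['distance']):.4f}",
            "-" * 58,
            f"{'protein':<16}{'ratio b/a':>10}{'t':>9}{'p':>11}{'distance':>10}",
        ]
        show = f.sort_values("p_value").head(top)
        for pid, r in show.iterrows():
            ratio = r["total_b"] / r["total_a"] if r["total_a"] > 0 else np.inf
            lines.append(f"{pid:<16}{ratio:>10.3f}{r['welch_t']:>9.2f}"
                         f"{r['p_value']:>11.3g}{r['distance']:>10.3f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_profile(self, protein: str, ax=None):
        """Overlay the two group-mean profiles with SD error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        x = np.arange(1, self.model.matrix.n_slices + 1)
        for group, color in ((self.model.group_a, "tab:red"),
                             (self.model.group_b, "tab:blue")):
            gp = group_mean_profile(self.model.matrix, group, protein)
            ax.errorbar(x, gp.mean, yerr=gp.sd, label=group, color=color,
                        lw=1.2, capsize=2)
        ax.set_xlabel("gel slice (top → bottom)")
        ax.set_ylabel("ion intensity")
        ax.set_title(protein)
        ax.legend(frameon=False)
        return ax
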