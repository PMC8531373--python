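"""PCA of standardized population mean profiles, with held-out projection.

The model is an eigendecomposition of the covariance matrix of the
fit-set profiles (rows = population samples, columns = the standardized
13-measurement battery).  The inputs are already z-scored against the
analysis-wide reference, so no second per-variable rescaling is applied
— the covariance, not correlation, matrix is decomposed.

Conventions follow standard craniometric practice:

* components are ordered by decreasing eigenvalue; a component's
  *contribution rate* is its eigenvalue as a percentage of total
  variance;
* the eigenvector sign indeterminacy is fixed by flipping any column
  whose loading sum is negative, so the overall-size axis (typically
  PC1, with near-equal positive loadings on every measurement) scores
  large crania positively;
* retention is by strict ``eigenvalue > 1`` (Kaiser-style) or strict
  ``contribution > p%``;
* held-out samples (e.g. single ancient crania) are *projected* onto
  the fitted axes — centered on the fit-set means and multiplied by the
  loadings — without altering the model.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CranioPCA", "PCAResults"]


class CranioPCA:
    """Principal component model of standardized profiles.

    Parameters
    ----------
    profiles
        DataFrame of standardized profiles (rows = sample ids, columns
        = battery codes).  May include samples that are only projected.
    fit_ids
        Sample ids used to fit the axes; defaults to all rows.  Rows
        not in ``fit_ids`` are projected as supplementary points.
    groups
        Optional mapping of sample id to group tag, carried into score
        exports.
    """

    def __init__(
        self,
        profiles: pd.DataFrame,
        fit_ids: Sequence[str] | None = None,
        groups: dict[str, str] | None = None,
    ):
        if profiles.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if profiles.isna().to_numpy().any():
            raise ValueError("profiles contain missing values; complete the battery first")
        self.profiles = profiles.astype(float)
        self.battery = tuple(profiles.columns)
        if fit_ids is None:
            fit_ids = list(profiles.index)
        missing = [i for i in fit_ids if i not in profiles.index]
        if missing:
            raise ValueError(f"fit_ids not in profile table: {missing}")
        self.fit_ids = tuple(fit_ids)
        self.groups = dict(groups or {})

    def fit(self) -> "PCAResults":
        X = self.profiles.loc[list(self.fit_ids)].to_numpy()
        n, p = X.shape
        if n <= p:
            import warnings

            warnings.warn(
                f"fit set has {n} samples for {p} variables; "
                "eigenstructure may be rank-deficient",
                stacklevel=2,
            )
        center = X.mean(axis=0)
        Xc = X - center
        cov = Xc.T @ Xc / (n - 1)
        eigval, eigvec = np.linalg.eigh(cov)
        idx = np.argsort(eigval)[::-1]
        eigval = np.clip(eigval[idx], 0.0, None)
        eigvec = eigvec[:, idx]
        # sign convention: loading sums non-negative (size axis positive)
        flip = eigvec.sum(axis=0) < 0
        eigvec[:, flip] *= -1.0
        rank = int(np.linalg.matrix_rank(cov))
        k = min(rank, p)
        return PCAResults(
            model=self,
            center=pd.Series(center, index=list(self.battery)),
            eigenvalues=eigval[:k],
            loadings=pd.DataFrame(
                eigvec[:, :k],
                index=list(self.battery),
                columns=[f"PC{i + 1}" for i in range(k)],
            ),
            total_variance=float(eigval.sum()),
        )


class PCAResults:
    """Fitted eigenstructure, scores, and supplementary projections."""

    def __init__(
        self,
        model: CranioPCA,
        center: pd.Series,
        eigenvalues: np.ndarray,
        loadings: pd.DataFrame,
        total_variance: float,
    ):
        self.model = model
        self.center = center
        self.eigenvalues = np.asarray(eigenvalues, dtype=float)
        self.loadings = loadings
        self.total_variance = total_variance
        self.fitted_ids = tuple(model.fit_ids)

    # -- basic quantities ---------------------------------------------------

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    @property
    def contribution(self) -> np.ndarray:
        """Per-component percentage of total variance."""
        if self.total_variance == 0:
            return np.zeros_like(self.eigenvalues)
        return 100.0 * self.eigenvalues / self.total_variance

    @property
    def cumulative_contribution(self) -> np.ndarray:
        return np.cumsum(self.contribution)

    def retained_components(
        self, rule: str = "eigenvalue_gt_1", p: float = 10.0
    ) -> list[int]:
        """Component indices (1-based) kept under a retention rule.

        ``"eigenvalue_gt_1"`` keeps eigenvalues strictly greater than 1;
        ``"contribution_gt_pct"`` keeps contribution rates strictly
        greater than ``p`` percent.
        """
        if rule == "eigenvalue_gt_1":
            keep = self.eigenvalues > 1.0
        elif rule == "contribution_gt_pct":
            keep = self.contribution > p
        else:
            raise ValueError(f"unknown retention rule {rule!r}")
        return [i + 1 for i, k in enumerate(keep) if k]

    # -- scores -------------------------------------------------------------

    def project(self, profile: pd.Series | pd.DataFrame) -> pd.Series | pd.DataFrame:
        """Score a profile (or table of profiles) on the fitted axes."""
        if isinstance(profile, pd.Series):
            return self.project(profile.to_frame().T).iloc[0]
        missing = [c for c in self.model.battery if c not in profile.columns]
        if missing:
            raise ValueError(f"profile lacks battery codes: {missing}")
        X = profile[list(self.model.battery)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("profile contains missing values")
        scores = (X - self.center.to_numpy()) @ self.loadings.to_numpy()
        return pd.DataFrame(scores, index=profile.index, columns=self.loadings.columns)

    @property
    def scores(self) -> pd.DataFrame:
        """Score table for all profiles, with a fitted/projected role flag."""
        table = self.project(self.model.profiles)
        table["role"] = [
            "fitted" if i in set(self.fitted_ids) else "projected"
            for i in table.index
        ]
        return table

    def rank_by_component(
        self, component: int, direction: str = "negative", top: int | None = None
    ) -> list[str]:
        """Sample ids ordered by a component's score; ties broken by id.

        ``direction="negative"`` puts the most negative scores first
        (e.g. the smallest crania on the size axis).
        """
        col = f"PC{component}"
        if col not in self.loadings.columns:
            raise ValueError(f"unknown component {component}")
        s = self.scores[col]
        ascending = direction == "negative"
        if direction not in ("negative", "positive"):
            raise ValueError("direction must be 'negative' or 'positive'")
        ordered = sorted(s.items(), key=lambda kv: ((kv[1] if ascending else -kv[1]), kv[0]))
        ids = [k for k, _ in ordered]
        return ids if top is None else ids[:top]

    # -- exports ------------------------------------------------------------

    def export_scatter(self, cx: int, cy: int, path: str | Path) -> Path:
        """CSV of (id, group_tag, score_x, score_y, role) for two components."""
        path = Path(path)
        sc = self.scores
        for c in (cx, cy):
            if f"PC{c}" not in sc.columns:
                raise ValueError(f"unknown component {c}")
        out = pd.DataFrame(
            {
                "sample_id": sc.index,
                "group_tag": [self.model.groups.get(i, "") for i in sc.index],
                f"PC{cx}": sc[f"PC{cx}"].to_numpy(),
                f"PC{cy}": sc[f"PC{cy}"].to_numpy(),
                "role": sc["role"].to_numpy(),
            }
        )
        out.to_csv(path, index=False)
        return path

    def export_loadings(self, path: str | Path) -> Path:
        """CSV of loadings with eigenvalue/contribution header rows."""
        path = Path(path)
        table = self.loadings.copy()
        table.loc["eigenvalue"] = self.eigenvalues
        table.loc["contribution_pct"] = self.contribution
        table.loc["cumulative_pct"] = self.cumulative_contribution
        table.to_csv(path, index_label="measurement")
        return path

    def summary(self) -> str:
        lines = [
            "Principal component analysis of standardized cranial profiles",
            "=" * 62,
            f"fitted samples:     {len(self.fitted_ids)}",
            f"projected samples:  {len(self.model.profiles) - len(self.fitted_ids)}",
            f"battery:            {' '.join(self.model.battery)}",
            "",
            f"{'component':>10} {'eigenvalue':>12} {'contrib %':>10} {'cum %':>8}",
        ]
        cum = self.cumulative_contribution
        for i, (ev, c) in enumerate(zip(self.eigenvalues, self.contribution)):
            lines.append(f"{'PC' + str(i + 1):>10} {ev:>12.4f} {c:>10.2f} {cum[i]:>8.2f}")
        kaiser = self.retained_components("eigenvalue_gt_1")
        pct = self.retained_components("contribution_gt_pct", p=10.0)
        lines += [
            "",
            f"retained (eigenvalue > 1):   {kaiser}",
            f"retained (contribution>10%): {pct}",
        ]
        return "\n".join(lines)
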