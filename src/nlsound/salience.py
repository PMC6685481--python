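"""Feature-table assembly and correlation-based pruning to salient measures.

Objective measures that share most of their variance carry redundant
information; the pruning rule removes, within each domain (temporal or
spectral) independently, measures whose absolute pairwise Pearson
correlation reaches a threshold (default 0.45), keeping one member of
every correlated group.  Removal is greedy and fully deterministic, and
every drop is recorded in an audit log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureTable",
    "CorrelationMatrix",
    "SalienceResult",
    "ConstantColumnError",
    "pearson_matrix",
    "select_salient",
    "CANONICAL_SALIENT_SEVEN",
]

#: The canonical seven-measure salient set (four temporal, three spectral)
#: that replication-style runs can force via a keep-list.
CANONICAL_SALIENT_SEVEN = (
    "nld_fd",
    "mean_peak_relative_amplitude",
    "permutation_entropy",
    "lz_differential_binary",
    "hnr",
    "mean_spectral_centroid",
    "rms_1000_2000",
)


class ConstantColumnError(ValueError):
    """A measure column is constant and cannot enter correlation analyses."""


@dataclass
class FeatureTable:
    """Sounds x objective measures, each measure tagged with a domain.

    ``data`` is indexed by sound_id; ``domains`` maps every column to
    ``"temporal"`` or ``"spectral"``.  Missing values are NaN.
    """

    data: pd.DataFrame
    domains: dict[str, str]

    def validate(self) -> None:
        missing = set(self.data.columns) - set(self.domains)
        if missing:
            raise ValueError(f"columns without domain tag: {sorted(missing)}")
        bad = [d for d in self.domains.values()
               if d not in ("temporal", "spectral")]
        if bad:
            raise ValueError(f"unknown domain tags: {sorted(set(bad))}")
        for col in self.data.columns:
            vals = self.data[col].dropna()
            if len(vals) and vals.nunique() <= 1:
                raise ConstantColumnError(
                    f"measure {col!r} is constant across the bank")

    def columns_in_domain(self, domain: str) -> list[str]:
        return [c for c in self.data.columns
                if self.domains.get(c) == domain]

    def to_csv(self, path_or_buf) -> None:
        """Write with 'measure:domain' column headers."""
        out = self.data.copy()
        out.columns = [f"{c}:{self.domains[c]}" for c in out.columns]
        out.to_csv(path_or_buf, index_label="sound_id")

    @classmethod
    def from_csv(cls, path_or_buf) -> "FeatureTable":
        df = pd.read_csv(path_or_buf, index_col="sound_id")
        domains = {}
        cols = []
        for c in df.columns:
            name, _, dom = c.rpartition(":")
            if not name:
                raise ValueError(f"column {c!r} lacks a ':domain' tag")
            domains[name] = dom
            cols.append(name)
        df.columns = cols
        df.index = df.index.astype(str)
        return cls(df, domains)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix with per-pair p-values and sample sizes."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    @property
    def names(self) -> list[str]:
        return list(self.r.columns)


def pearson_matrix(table: FeatureTable | pd.DataFrame) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    Requires at least 3 complete observations per pair and no constant
    column (over its non-missing rows).
    """
    df = table.data if isinstance(table, FeatureTable) else table
    if isinstance(table, FeatureTable):
        table.validate()
    else:
        for col in df.columns:
            vals = df[col].dropna()
            if len(vals) and vals.nunique() <= 1:
                raise ConstantColumnError(f"column {col!r} is constant")
    cols = list(df.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(df))
    for i in range(k):
        n[i, i] = df[cols[i]].notna().sum()
        for j in range(i + 1, k):
            pair = df[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for "
                    f"({cols[i]!r}, {cols[j]!r})")
            res = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
            n[i, j] = n[j, i] = len(pair)
    idx = pd.Index(cols)
    return CorrelationMatrix(pd.DataFrame(r, idx, idx),
                             pd.DataFrame(p, idx, idx),
                             pd.DataFrame(n, idx, idx))


@dataclass
class SalienceResult:
    """Retained measures per domain plus a drop-by-drop audit log."""

    retained: dict[str, list[str]]
    audit: list[str] = field(default_factory=list)
    forced: bool = False

    @property
    def all_retained(self) -> list[str]:
        out = []
        for domain in sorted(self.retained):
            out.extend(self.retained[domain])
        return out

    def audit_text(self) -> str:
        return "\n".join(self.audit)


def select_salient(corr: CorrelationMatrix, threshold: float,
                   domains: dict[str, str],
                   forced_keep: list[str] | None = None) -> SalienceResult:
    """Greedy within-domain pruning of measures correlated at |r| >= threshold.

    Repeatedly drops the measure with the most over-threshold partners in
    its domain; ties go to the measure with the larger mean |r| to the
    remaining measures, then to the lexicographically smallest name.
    Cross-domain correlations never cause a drop.  A ``forced_keep`` list
    bypasses pruning and imposes the retained set directly (for
    replication-style runs).
    """
    names = corr.names
    if not names:
        raise ValueError("empty correlation matrix")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")

    if forced_keep is not None:
        unknown = [m for m in forced_keep if m not in names]
        if unknown:
            raise ValueError(f"forced keep-list not in table: {unknown}")
        retained: dict[str, list[str]] = {}
        for m in forced_keep:
            retained.setdefault(domains[m], []).append(m)
        audit = [f"forced keep-list imposed; retained {len(forced_keep)} "
                 f"of {len(names)} measures"]
        return SalienceResult(retained, audit, forced=True)

    retained = {}
    audit = []
    abs_r = corr.r.abs()
    by_domain: dict[str, list[str]] = {}
    for m in names:
        by_domain.setdefault(domains[m], []).append(m)
    for domain in sorted(by_domain):
        keep = sorted(by_domain[domain])
        while True:
            sub = abs_r.loc[keep, keep]
            over = (sub.values >= threshold).sum(axis=0) - 1  # minus diagonal
            if over.max() <= 0:
                break
            worst = over.max()
            cand = [m for m, o in zip(keep, over) if o == worst]
            if len(cand) > 1:
                mean_r = {m: (sub.loc[m].sum() - 1) / (len(keep) - 1)
                          for m in cand}
                top = max(mean_r.values())
                cand = sorted(m for m in cand if mean_r[m] >= top - 1e-12)
            drop = cand[0]
            partners = [m for m in keep
                        if m != drop and abs_r.loc[drop, m] >= threshold]
            audit.append(
                f"[{domain}] drop {drop!r}: {len(partners)} partner(s) with "
                f"|r| >= {threshold:g} ({', '.join(partners)})")
            keep.remove(drop)
        retained[domain] = keep
        audit.append(f"[{domain}] retained: {', '.join(keep)}")
    return SalienceResult(retained, audit)
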