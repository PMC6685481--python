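"""End-to-end analysis pipeline: extract measures, prune, map to percepts.

The full sequence mirrors the standard workflow for relating objective
sound structure to listener ratings:

1. percept inter-correlation (with the familiarity-redundancy flag);
2. measure correlation matrix and within-domain salience pruning;
3. simple regressions of each percept on each salient measure;
4. within-domain pair and full-domain multiple regressions;
5. one-way ANOVAs of percepts and salient measures across source
   categories, with a significant-pair tally;
6. Ward clustering on each domain's raw measures at several cut levels,
   with percept ANOVAs across clusters;
7. per-domain PCA and clustering on the first two PC scores, again with
   percept ANOVAs.

Everything is deterministic given the inputs and config; the report
manifest records the config hash and seed so a run can be replayed
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from . import __version__
from .perception_mapping import (
    CORE_PERCEPTS,
    RatingsTable,
    category_anova,
    cluster_percept_comparison,
    homogeneity_tally,
    multiple_regression,
    pca,
    percept_intercorrelation,
    simple_regressions,
)
from .salience import FeatureTable, pearson_matrix, select_salient
from .signal_io import Waveform, read_metadata_csv, read_wav
from .spectral_features import (
    SpectralConfig,
    band_rms,
    harmonicity_hnr,
    mean_spectral_centroid,
    spectral_flatness,
    spectral_structure_index,
)
from .temporal_features import (
    TemporalConfig,
    binarize,
    duration_s,
    entropy_window,
    higuchi_fd,
    lz_complexity,
    nld_fd,
    peak_measures,
    permutation_entropy,
    sample_entropy,
)

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "extract_features",
    "extract_features_from_bank",
    "run_full_analysis",
    "MEASURE_DOMAINS",
]

log = logging.getLogger("nlsound")

#: The default 19-measure battery and its domain tags (10 temporal,
#: 9 spectral).
MEASURE_DOMAINS = {
    "sample_entropy": "temporal",
    "permutation_entropy": "temporal",
    "lz_differential_binary": "temporal",
    "lz_average_binary": "temporal",
    "lz_modified_zone_binary": "temporal",
    "higuchi_fd": "temporal",
    "nld_fd": "temporal",
    "num_peaks": "temporal",
    "mean_peak_relative_amplitude": "temporal",
    "duration": "temporal",
    "mean_spectral_centroid": "spectral",
    "rms_0_500": "spectral",
    "rms_500_1000": "spectral",
    "rms_1000_2000": "spectral",
    "rms_2000_4000": "spectral",
    "rms_4000_8000": "spectral",
    "hnr": "spectral",
    "spectral_flatness": "spectral",
    "spectral_structure_index": "spectral",
}


@dataclass
class AnalysisConfig:
    """Aggregated pipeline parameters, serializable to a single YAML file."""

    temporal: TemporalConfig = field(default_factory=TemporalConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    salience_threshold: float = 0.45
    forced_keep: list[str] | None = None
    cluster_levels: list[int] = field(default_factory=lambda: [10, 5, 3, 2])
    alpha: float = 0.05
    redundancy_r: float = 0.7
    min_cluster_size: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spectral"]["bands"] = [list(b) for b in d["spectral"]["bands"]]
        d["temporal"]["nld_calibration"] = list(
            d["temporal"]["nld_calibration"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        known = {"temporal", "spectral", "salience_threshold", "forced_keep",
                 "cluster_levels", "alpha", "redundancy_r",
                 "min_cluster_size", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "temporal" in d:
            t = dict(d["temporal"])
            if "nld_calibration" in t:
                t["nld_calibration"] = tuple(t["nld_calibration"])
            d["temporal"] = TemporalConfig(**t)
        if "spectral" in d:
            s = dict(d["spectral"])
            if "bands" in s:
                s["bands"] = tuple(tuple(b) for b in s["bands"])
            d["spectral"] = SpectralConfig(**s)
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _measures_for(w: Waveform, tcfg: TemporalConfig,
                  scfg: SpectralConfig) -> dict[str, float]:
    x = w.samples
    ent = entropy_window(x, w.sample_rate, tcfg)
    r = tcfg.sampen_r_factor * ent.std()
    out = {
        "sample_entropy": sample_entropy(ent, tcfg.sampen_m, r),
        "permutation_entropy": permutation_entropy(
            ent, tcfg.pe_order, tcfg.pe_delay),
        "higuchi_fd": higuchi_fd(x, tcfg.higuchi_kmax),
        "nld_fd": nld_fd(x, tcfg.nld_window, tcfg.nld_calibration),
        "duration": duration_s(w),
    }
    for coding, name in (("differential_binary", "lz_differential_binary"),
                         ("average_binary", "lz_average_binary"),
                         ("modified_zone_binary", "lz_modified_zone_binary")):
        bits = binarize(ent, coding, tcfg.lz_zone_factor)
        out[name] = lz_complexity(bits, normalized=True)
    out.update(peak_measures(x, w.sample_rate, tcfg))
    scfg.validate_rate(w.sample_rate)
    out["mean_spectral_centroid"] = mean_spectral_centroid(w, scfg)
    for low, high in scfg.bands:
        out[f"rms_{int(low)}_{int(high)}"] = band_rms(w, low, high, scfg)
    out["hnr"] = harmonicity_hnr(w, scfg)
    out["spectral_flatness"] = spectral_flatness(w, scfg)
    out["spectral_structure_index"] = spectral_structure_index(w, scfg)
    return out


def extract_features_from_bank(bank: list[Waveform],
                               config: AnalysisConfig | None = None
                               ) -> FeatureTable:
    """Compute the full measure battery for a list of in-memory waveforms.

    Per-(sound, measure) failures are recorded as NaN with a logged
    warning; the run continues.  Raises if no sound yields any measure.
    """
    config = config or AnalysisConfig()
    rows = {}
    t0 = time.monotonic()
    for w in bank:
        try:
            rows[w.sound_id] = _measures_for(w, config.temporal,
                                             config.spectral)
        except Exception as exc:
            log.warning("sound %s failed entirely: %s", w.sound_id, exc)
    if not rows:
        raise ValueError("no sound produced any measure")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sound_id"
    domains = {c: MEASURE_DOMAINS.get(c, "spectral" if c.startswith("rms_")
                                      else "temporal")
               for c in df.columns}
    log.info("extracted %d measures for %d sounds in %.1fs",
             df.shape[1], df.shape[0], time.monotonic() - t0)
    return FeatureTable(df, domains)


def extract_features(sound_dir: str, metadata_csv: str,
                     config: AnalysisConfig | None = None) -> FeatureTable:
    """Read WAVs listed in a metadata CSV and extract all measures.

    Unreadable sounds are dropped with a logged warning; an error is
    raised only if no sound can be read.
    """
    meta = read_metadata_csv(metadata_csv)
    bank = []
    for _, row in meta.iterrows():
        path = row["path"]
        if not os.path.isabs(path):
            path = os.path.join(sound_dir, path)
        try:
            bank.append(read_wav(path, sound_id=row["sound_id"],
                                 category=row["category"]))
        except Exception as exc:
            log.warning("skipping sound %s: %s", row["sound_id"], exc)
    if not bank:
        raise ValueError("zero readable sounds")
    return extract_features_from_bank(bank, config)


@dataclass
class AnalysisReport:
    """All numeric outputs of one full pipeline run plus a manifest."""

    features: FeatureTable
    percept_corr: object | None
    percept_redundancy_flags: list[str]
    measure_corr: object
    salience: object
    table_simple: pd.DataFrame | None  # measure x percept r/p (long)
    table_pairs: pd.DataFrame | None  # same-domain pairs x percept R^2
    table_domains: pd.DataFrame | None  # full-domain sets x percept R^2
    category_anovas: dict
    category_tally: dict | None
    cluster_raw: dict
    cluster_pca: dict
    pca_results: dict
    manifest: dict

    def simple_matrix(self) -> pd.DataFrame | None:
        """Measures x percepts matrix of Pearson r (Table-3-style layout)."""
        if self.table_simple is None:
            return None
        return self.table_simple.pivot(index="measure", columns="percept",
                                       values="r")

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        j = os.path.join
        self.features.to_csv(j(outdir, "features.csv"))
        self.measure_corr.r.to_csv(j(outdir, "measure_correlations.csv"))
        with open(j(outdir, "salience_audit.txt"), "w") as fh:
            fh.write(self.salience.audit_text() + "\n")
        pd.Series(self.salience.all_retained, name="measure").to_csv(
            j(outdir, "salient_measures.csv"), index=False)
        if self.percept_corr is not None:
            self.percept_corr.r.to_csv(j(outdir, "percept_correlations.csv"))
        if self.table_simple is not None:
            self.table_simple.to_csv(j(outdir, "regressions_simple.csv"),
                                     index=False)
        if self.table_pairs is not None:
            self.table_pairs.to_csv(j(outdir, "regressions_pairs.csv"),
                                    index=False)
        if self.table_domains is not None:
            self.table_domains.to_csv(j(outdir, "regressions_domains.csv"),
                                      index=False)
        anova_rows = []
        for name, res in self.category_anovas.items():
            anova_rows.append({
                "response": res.response, "grouping": res.grouping,
                "F": res.f, "p": res.p,
                "brown_forsythe_p": res.brown_forsythe_p,
                "significant_pairs": res.significant_pairs,
                "unreliable": res.unreliable})
        if anova_rows:
            pd.DataFrame(anova_rows).to_csv(
                j(outdir, "category_anovas.csv"), index=False)
        cluster_rows = []
        for space, results in (("raw", self.cluster_raw),
                               ("pca", self.cluster_pca)):
            for domain, levels in results.items():
                for k, entry in levels.items():
                    for pct, res in entry["anova"].items():
                        cluster_rows.append({
                            "space": space, "domain": domain, "k": k,
                            "percept": pct, "F": res.f, "p": res.p,
                            "significant_pairs": res.significant_pairs,
                            "small_clusters_excluded":
                                len(entry["small_clusters"])})
        if cluster_rows:
            pd.DataFrame(cluster_rows).to_csv(
                j(outdir, "cluster_anovas.csv"), index=False)
        for domain, res in self.pca_results.items():
            res.loadings.to_csv(j(outdir, f"pca_{domain}_loadings.csv"))
            res.scores.to_csv(j(outdir, f"pca_{domain}_scores.csv"))
        with open(j(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _pair_and_domain_tables(features, salience, ratings, alpha):
    pair_rows, domain_rows = [], []
    for domain in sorted(salience.retained):
        cols = salience.retained[domain]
        for a, b in combinations(sorted(cols), 2):
            for pct in CORE_PERCEPTS:
                res = multiple_regression(features, [a, b], ratings, pct)
                pair_rows.append({
                    "domain": domain, "predictors": f"{a}+{b}",
                    "percept": pct, "r_squared": res.r_squared,
                    "p": res.p, "n": res.n})
        if len(cols) >= 2:
            for pct in CORE_PERCEPTS:
                res = multiple_regression(features, sorted(cols), ratings,
                                          pct)
                domain_rows.append({
                    "domain": domain, "predictors": "+".join(sorted(cols)),
                    "percept": pct, "r_squared": res.r_squared,
                    "p": res.p, "n": res.n})
    return pd.DataFrame(pair_rows), pd.DataFrame(domain_rows)


def run_full_analysis(features: FeatureTable,
                      ratings: RatingsTable | None,
                      config: AnalysisConfig | None = None,
                      categories: pd.Series | None = None) -> AnalysisReport:
    """Execute the full analysis sequence and assemble the report.

    ``ratings`` may be None, in which case only the feature/salience half
    of the report (stages 2 and the PCA of stage 7) is produced.
    ``categories`` maps sound_id to source category for the category
    ANOVAs; omitted, that stage is skipped.
    """
    config = config or AnalysisConfig()
    features.validate()

    percept_corr, flags = (None, [])
    if ratings is not None:
        ratings.validate()
        percept_corr, flags = percept_intercorrelation(
            ratings, config.redundancy_r)
        log.info("stage percept_intercorrelation: flags=%s", flags)

    measure_corr = pearson_matrix(features)
    salience = select_salient(measure_corr, config.salience_threshold,
                              features.domains, config.forced_keep)
    log.info("stage salience: retained %d measures",
             len(salience.all_retained))

    table_simple = table_pairs = table_domains = None
    category_anovas: dict = {}
    tally = None
    cluster_raw: dict = {}
    cluster_pca: dict = {}
    if ratings is not None:
        salient = salience.all_retained
        table_simple = simple_regressions(features, ratings, salient)
        table_pairs, table_domains = _pair_and_domain_tables(
            features, salience, ratings, config.alpha)
        log.info("stage regressions: %d simple, %d pairs",
                 len(table_simple), len(table_pairs))
        if categories is not None:
            cats = categories.astype(str)
            for pct in CORE_PERCEPTS:
                category_anovas[f"percept:{pct}"] = category_anova(
                    ratings.data[pct], cats.reindex(ratings.data.index),
                    alpha=config.alpha, response_name=pct)
            for m in salient:
                category_anovas[f"measure:{m}"] = category_anova(
                    features.data[m], cats.reindex(features.data.index),
                    alpha=config.alpha, response_name=m)
            k_groups = len(next(iter(category_anovas.values())).groups_used)
            tally = homogeneity_tally(list(category_anovas.values()),
                                      k_groups)
            log.info("stage category_anova: tally=%s", tally)
        for domain in ("temporal", "spectral"):
            cols = [c for c in salience.all_retained
                    if features.domains[c] == domain]
            sub = FeatureTable(features.data[cols],
                               {c: domain for c in cols})
            if len(cols) < 2:
                continue
            cluster_raw[domain] = cluster_percept_comparison(
                sub, ratings, domain, config.cluster_levels, use_pca=False,
                alpha=config.alpha, min_cluster_size=config.min_cluster_size)
            cluster_pca[domain] = cluster_percept_comparison(
                sub, ratings, domain, config.cluster_levels, use_pca=True,
                alpha=config.alpha, min_cluster_size=config.min_cluster_size)
        log.info("stage clustering: levels=%s", config.cluster_levels)

    pca_results = {}
    for domain in ("temporal", "spectral"):
        cols = [c for c in salience.all_retained
                if features.domains.get(c) == domain]
        if len(cols) >= 2 and len(features.data) > len(cols):
            pca_results[domain] = pca(
                FeatureTable(features.data[cols], {c: domain for c in cols}))

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_sounds": int(len(features.data)),
        "n_measures": int(features.data.shape[1]),
        "nlsound_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    return AnalysisReport(
        features=features, percept_corr=percept_corr,
        percept_redundancy_flags=flags, measure_corr=measure_corr,
        salience=salience, table_simple=table_simple,
        table_pairs=table_pairs, table_domains=table_domains,
        category_anovas=category_anovas, category_tally=tally,
        cluster_raw=cluster_raw, cluster_pca=cluster_pca,
        pca_results=pca_results, manifest=manifest)
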