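"""End-to-end orchestration of the fingerprinting study as a configured run.

``run_study`` executes the full chain — preprocess → subset search →
jackknife/bootstrap → ANOVA/Tukey → ANOSIM/NMDS (temporal and collection
method) → settler projection / extra-baseline probability / mixed-stock MLE
→ mixture clustering — honoring stage toggles, with every stochastic stage
seeded from the config.  The resulting :class:`ReportBundle` serializes to
JSON with a provenance block (config hash, seeds, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_preprocess import (
    ElementRatioTable, SignatureSet, average_replicate_ablations,
    drop_low_detection_elements, log_standardize, log_transform, remove_outliers,
)
from .lda import fit_lda
from .selection import bootstrap_accuracy, exhaustive_subset_search, jackknife_accuracy
from .univariate import elementwise_anova_table
from .ordination import anosim, gower_dissimilarity, nmds
from .assignment import (extra_baseline_probability, fit_baseline,
                         mle_mixture_proportions, project_settlers)
from .mixture import select_num_sources

__all__ = ["StudyConfig", "ReportBundle", "validate_config", "run_study",
           "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "level": "region",
    "max_below_lod_fraction": 0.5,
    "outlier_threshold": 3.5,
    "priors": "proportional",
    "stages": {
        "classification": True,
        "univariate": True,
        "ordination": True,
        "assignment": True,
        "clustering": True,
    },
    "bootstrap": {"reps": 5000, "train_fraction": 0.9, "seed": None},
    "ordination": {"n_permutations": 999, "n_starts": 100, "seed": None,
                   "epoch_boundary": "2015-07-05"},
    "assignment": {"baseline_elements": ["Mn", "Sr"], "level": 0.95,
                   "mle_bootstrap": 500, "seed": None},
    "clustering": {"k_max": 4, "n_iter": 2000, "burn_in": 500,
                   "n_chains": 3, "seed": None},
}

_STAGE_SEED_KEYS = {
    "classification": ("bootstrap", "seed"),
    "ordination": ("ordination", "seed"),
    "assignment": ("assignment", "seed"),
    "clustering": ("clustering", "seed"),
}


@dataclass
class StudyConfig:
    settings: dict

    def __getitem__(self, key):
        return self.settings[key]

    def hash(self) -> str:
        blob = json.dumps(self.settings, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _merge(base: dict, override: dict, path="") -> tuple[dict, list[str]]:
    out = dict(base)
    violations = []
    for k, v in override.items():
        if k not in base:
            violations.append(f"unknown key: {path}{k}")
            continue
        if isinstance(base[k], dict) and isinstance(v, dict):
            out[k], sub = _merge(base[k], v, f"{path}{k}.")
            violations.extend(sub)
        else:
            out[k] = v
    return out, violations


def validate_config(source) -> StudyConfig:
    """Validate a config mapping or YAML path against the study schema.

    Unknown keys and missing seeds for enabled stochastic stages are
    violations; defaults are filled in and echoed in the returned object.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    merged, violations = _merge(DEFAULT_CONFIG, raw)
    for stage, (sect, key) in _STAGE_SEED_KEYS.items():
        if merged["stages"].get(stage) and merged[sect][key] is None:
            violations.append(
                f"missing seed: {sect}.{key} (stage '{stage}' is enabled)")
    if merged["level"] not in {"region", "site"}:
        violations.append("level must be 'region' or 'site'")
    if violations:
        raise ValueError("invalid study config: " + "; ".join(violations))
    return StudyConfig(merged)


@dataclass
class ReportBundle:
    provenance: dict
    preprocessing: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)
    univariate: pd.DataFrame | None = None
    ordination: dict = field(default_factory=dict)
    assignment: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, pd.DataFrame):
                return json.loads(o.to_json())
            if isinstance(o, pd.Series):
                return o.to_dict()
            raise TypeError(f"not serializable: {type(o)}")

        d = {k: v for k, v in asdict(self).items()}
        d["univariate"] = (json.loads(self.univariate.to_json())
                           if self.univariate is not None else None)
        text = json.dumps(d, indent=1, default=default, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def preprocess(broods: ElementRatioTable, config: StudyConfig):
    """LOD screening → replicate averaging → log transform → outlier removal."""
    table, removed = drop_low_detection_elements(
        broods, config["max_below_lod_fraction"])
    sig = average_replicate_ablations(table)
    sig_log = log_transform(sig)
    sig_clean, outliers = remove_outliers(
        sig_log, threshold=config["outlier_threshold"],
        group_by=config["level"])
    sig_z, params = log_standardize(sig_clean)
    info = {"elements_removed_lod": removed,
            "outliers_removed": outliers.removed,
            "outlier_rule": outliers.rule,
            "n_samples": sig_clean.n,
            "panel": sig_clean.elements}
    return sig_clean, sig_z, params, info


def run_study(config: StudyConfig, broods: ElementRatioTable,
              settlers: ElementRatioTable | None = None,
              method_comparison: ElementRatioTable | None = None) -> ReportBundle:
    """Run every enabled stage of the study on the supplied tables."""
    stages = config["stages"]
    bundle = ReportBundle(provenance={
        "config_hash": config.hash(),
        "config": config.settings,
        "version": __version__,
    })

    sig_log, sig_z, params, info = preprocess(broods, config)
    bundle.preprocessing = info
    level = config["level"]

    model = None
    winner = tuple(sig_z.elements)
    if stages.get("classification"):
        search = exhaustive_subset_search(sig_z, level, priors=config["priors"])
        winner = search.winner
        jk = jackknife_accuracy(sig_z, level, subset=winner, priors=config["priors"])
        boot = bootstrap_accuracy(
            sig_z, level, subset=winner,
            train_fraction=config["bootstrap"]["train_fraction"],
            reps=config["bootstrap"]["reps"], seed=config["bootstrap"]["seed"],
            priors=config["priors"])
        model = fit_lda(sig_z.select_elements(winner), level,
                        priors=config["priors"], transform_params=params)
        bundle.classification = {
            "winner_subset": list(winner),
            "n_subsets_scored": len(search.ranking),
            "jackknife": jk.to_dict(),
            "bootstrap": boot.to_dict(),
            "proportion_of_trace": model.proportion_of_trace.tolist(),
        }

    if stages.get("univariate"):
        sub = sig_log.select_elements(list(winner))
        bundle.univariate = elementwise_anova_table(sub, group_by=level)

    if stages.get("ordination"):
        ocfg = config["ordination"]
        seed = ocfg["seed"]
        results = {}
        boundary = np.datetime64(str(ocfg["epoch_boundary"]))
        dates = pd.to_datetime(sig_z.meta["date"]).to_numpy()
        epoch = np.where(dates <= boundary, "early", "late")
        for site_like in pd.unique(sig_z.meta["site"]):
            mask = (sig_z.meta["site"] == site_like).to_numpy()
            lab = epoch[mask]
            if len(np.unique(lab)) < 2 or min(np.bincount(pd.factorize(lab)[0])) < 2:
                continue
            d = gower_dissimilarity(
                SignatureSet(sig_z.values[mask], sig_z.meta[mask], sig_z.transform_state))
            res = anosim(d, lab, n_perm=ocfg["n_permutations"], seed=seed)
            nm = nmds(d, k=2, n_starts=min(ocfg["n_starts"], 25), seed=seed)
            results[f"temporal:{site_like}"] = {
                "R": res.R, "p": res.p_value, "stress": nm.stress,
                "n_early": int((lab == "early").sum()),
                "n_late": int((lab == "late").sum()),
            }
        if method_comparison is not None:
            mc_sig = average_replicate_ablations(method_comparison)
            mc_z, _ = log_standardize(log_transform(mc_sig))
            d = gower_dissimilarity(mc_z)
            lab = mc_z.meta["method"].to_numpy()
            res = anosim(d, lab, n_perm=ocfg["n_permutations"], seed=seed)
            nm = nmds(d, k=2, n_starts=min(ocfg["n_starts"], 25), seed=seed)
            results["method_comparison"] = {
                "R": res.R, "p": res.p_value, "stress": nm.stress}
        bundle.ordination = results

    if settlers is not None and stages.get("assignment") and model is not None:
        acfg = config["assignment"]
        settler_sig = average_replicate_ablations(settlers)
        report = project_settlers(model, settler_sig, level=acfg["level"])
        baseline_pair = fit_baseline(sig_log, acfg["baseline_elements"],
                                     group_by=level)
        outside_prob, flagged = extra_baseline_probability(
            baseline_pair, log_transform(settler_sig), acfg["level"])
        baseline_lda = fit_baseline(sig_log, list(winner), group_by=level)
        mix = mle_mixture_proportions(
            baseline_lda, log_transform(settler_sig),
            n_boot=acfg["mle_bootstrap"], seed=acfg["seed"])
        bundle.assignment = {
            "n_settlers": settler_sig.n,
            "outside_all_ellipses_fraction": report.outside_all_fraction,
            "extra_baseline_flagged_fraction": flagged,
            "baseline_elements": acfg["baseline_elements"],
            "mle_proportions": mix.proportions.to_dict(),
            "mle_ci_low": mix.ci_low.to_dict(),
            "mle_ci_high": mix.ci_high.to_dict(),
            "baseline_mismatch_warning": flagged > 0.5,
        }

    if settlers is not None and stages.get("clustering"):
        ccfg = config["clustering"]
        settler_sig = average_replicate_ablations(settlers)
        z, _ = log_standardize(log_transform(settler_sig))
        fit = select_num_sources(
            z.values.to_numpy(float), K_max=ccfg["k_max"], n_iter=ccfg["n_iter"],
            burn_in=ccfg["burn_in"], n_chains=ccfg["n_chains"], seed=ccfg["seed"])
        bundle.clustering = {
            "selected_K": fit.selected_K,
            "score_table": {str(k): v for k, v in fit.score_table.items()},
            "weights": fit.weights.tolist(),
            "n": int(z.n),
        }
    return bundle
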