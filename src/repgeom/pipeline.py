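"""End-to-end pipeline driver.

A declarative YAML (or dict) configuration names the stages to run, the
inputs (file paths or a synthetic-data specification), the knobs of each
stage, and the seeds. Stages run in the canonical order

    rdm -> ceiling -> compare -> categoricality -> reweight -> categorize

and results are written as delimited tables and RDM text files plus a
machine-readable run manifest recording seeds, package version, and
every knob in effect. Inputs are validated (stimulus-id agreement across
files) before any computation; an RDM over a subset of the model
stimulus ids is embedded automatically with missing cells, and the
embedding is logged in the manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .category_model import categoricality_test, clustering_strength_ci
from .categorization import kfold_accuracy
from .inference import bootstrap_stimuli, permutation_test
from .noise_ceiling import NoiseCeiling, SubjectEnsemble
from .rdm import read_features, read_rdm, write_rdm
from .recombination import ComponentSet, CrossValidatedReweighting
from .stimuli import StimulusSet
from .synthetic import (
    SyntheticSpec,
    generate_component_models,
    generate_mixture,
    generate_subject_ensemble,
)

log = logging.getLogger("repgeom")

DEFAULTS = {
    "seed": 0,
    "n_perm": 1000,
    "n_boot": 1000,
    "n_rand": 1000,
    "metric": "correlation",
    "holdout_size": 8,
    "max_folds": 50_000,
    "k_folds": 12,
    "svm_c": 1.0,
    "equate_to": None,
    "ceiling_max_iter": 50,
    "ceiling_tol": 0.0,
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as f:
            cfg = yaml.safe_load(f)
    else:
        cfg = dict(path_or_dict)
    merged = dict(DEFAULTS)
    merged.update(cfg or {})
    return merged


def _load_inputs(cfg: dict, rng: np.random.Generator):
    """Resolve inputs either from files or from a synthetic specification."""
    if "synthetic" in cfg:
        s = cfg["synthetic"] or {}
        spec = SyntheticSpec(
            n_stimuli=s.get("n_stimuli", 48),
            n_features=s.get("n_features", 60),
            tightness=s.get("tightness", {"animate": 1.0, "face": 0.6}),
            feature_noise_sd=s.get("feature_noise_sd", 1.0),
            n_subjects=s.get("n_subjects", 4),
            subject_noise_sd=s.get("subject_noise_sd", 0.15),
            seed=int(rng.integers(2**31)),
        )
        stimuli = spec.stimulus_set()
        components = generate_component_models(
            s.get("n_models", 4), spec, seed=int(rng.integers(2**31))
        )
        w = rng.uniform(0.2, 1.0, size=len(components))
        reference = generate_mixture(components, w, cell_noise_sd=0.0)
        ensemble = generate_subject_ensemble(
            reference, spec.n_subjects, spec.subject_noise_sd,
            seed=int(rng.integers(2**31)),
        )
        return stimuli, components, reference, ensemble, spec
    # file-based inputs
    stimuli = StimulusSet.from_frame(pd.read_csv(cfg["labels"], sep=None, engine="python"))
    models = [read_features(p, model_name=Path(p).stem) for p in cfg.get("models", [])]
    items = [(m.model_name, m) for m in models]
    components = ComponentSet.from_items(items) if items else None
    reference = read_rdm(cfg["reference_rdm"], cfg["metric"]) if cfg.get("reference_rdm") else None
    subject_rdms = [read_rdm(p, cfg["metric"]) for p in cfg.get("subject_rdms", [])]
    if reference is not None and set(reference.stimulus_ids) < set(stimuli.ids):
        log.info("embedding %d-stimulus reference into %d-stimulus frame",
                 reference.n_stimuli, len(stimuli))
        reference = reference.embed(stimuli.ids)
    ensemble = SubjectEnsemble(tuple(subject_rdms)) if len(subject_rdms) >= 2 else None
    return stimuli, components, reference, ensemble, None


def run_pipeline(config, out_dir) -> dict:
    """Execute the configured stages; returns the result bundle written to
    ``out_dir``."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg["seed"])
    stages = cfg.get("stages", ["rdm", "ceiling", "compare", "categoricality",
                                "reweight", "categorize"])
    stimuli, components, reference, ensemble, spec = _load_inputs(cfg, rng)
    results: dict = {"stages": {}}
    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "stages": stages,
        "config": {k: v for k, v in cfg.items() if k not in ("stages",)},
        "synthetic": spec is not None,
        "embedded_reference": reference is not None
        and bool(np.isnan(reference.values).any()),
    }

    if "rdm" in stages and components is not None:
        for name, r in zip(components.names, components.rdms):
            write_rdm(r, out / f"rdm_{name}.tsv")
        if reference is not None:
            write_rdm(reference, out / "rdm_reference.tsv")
        results["stages"]["rdm"] = {"n_rdms": len(components)}

    if "ceiling" in stages and ensemble is not None:
        nc = NoiseCeiling(max_iter=cfg["ceiling_max_iter"], tol=cfg["ceiling_tol"]).fit(ensemble)
        write_rdm(nc.consensus_rdm_, out / "consensus_rdm.tsv")
        results["stages"]["ceiling"] = {"lower": nc.lower_, "upper": nc.upper_,
                                        "n_subjects": nc.n_subjects_,
                                        "few_subjects_warning": nc.n_subjects_ < 3}

    if "compare" in stages and components is not None and reference is not None:
        strata = stimuli.members("animate")
        rows = []
        boot = bootstrap_stimuli(reference, list(components.rdms), strata,
                                 n_boot=cfg["n_boot"], seed=int(rng.integers(2**31)),
                                 candidate_names=list(components.names))
        for k, name in enumerate(components.names):
            pt = permutation_test(reference, components.rdms[k],
                                  n_perm=cfg["n_perm"], seed=int(rng.integers(2**31)))
            ceil = results["stages"].get("ceiling", {})
            rows.append({
                "candidate": name,
                "tau_a": pt.statistic,
                "se": boot.se[k],
                "p_perm": pt.p_value,
                "above_lower_bound": bool(ceil and pt.statistic >= ceil["lower"]),
            })
        table = pd.DataFrame(rows)
        table.to_csv(out / "compare.tsv", sep="\t", index=False)
        results["stages"]["compare"] = rows

    if "categoricality" in stages and reference is not None:
        tr = categoricality_test(reference, stimuli, n_rand=cfg["n_rand"],
                                 seed=int(rng.integers(2**31)))
        cs = clustering_strength_ci(reference, stimuli, n_boot=cfg["n_boot"],
                                    seed=int(rng.integers(2**31)))
        pd.DataFrame(cs["categories"]).T.to_csv(out / "categoricality.tsv", sep="\t")
        results["stages"]["categoricality"] = {
            "cci": tr.statistic, "p": tr.p_value, "betas": cs["categories"],
        }

    if "reweight" in stages and components is not None and reference is not None:
        strata = stimuli.members("animate").astype(int)
        cv = CrossValidatedReweighting(
            holdout_size=cfg["holdout_size"], max_folds=cfg["max_folds"],
            seed=int(rng.integers(2**31)),
        ).fit(components, reference, strata)
        write_rdm(cv.rdm_, out / "reweighted_rdm.tsv")
        pd.DataFrame(cv.fold_weights_, columns=list(components.names)).to_csv(
            out / "fold_weights.tsv", sep="\t", index=False)
        results["stages"]["reweight"] = {
            "n_folds": cv.n_folds_,
            "mean_weights": dict(zip(components.names,
                                     cv.mean_weights_.w.tolist())),
        }

    if "categorize" in stages and spec is not None:
        from .synthetic import generate_model_features

        fm = generate_model_features(
            SyntheticSpec(n_stimuli=spec.n_stimuli, n_features=spec.n_features,
                          tightness=spec.tightness, seed=int(rng.integers(2**31))))
        acc = kfold_accuracy(fm, stimuli.members("animate").astype(int),
                             k=cfg["k_folds"], seed=int(rng.integers(2**31)),
                             C=cfg["svm_c"])
        results["stages"]["categorize"] = {"animate_accuracy": acc}

    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    with open(out / "results.json", "w") as f:
        json.dump(results, f, indent=2, default=float)
    return results
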