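"""End-to-end study workflow.

simulate (or load) -> claims features -> latent class reference -> model-based
classifiers (full and BIC-best logistic, recursive-partitioning tree) and the
expert rule -> accuracy evaluation against both the latent reference and the
endoscopist indication — and, on synthetic data where the true latent
indication is known, against the truth itself (the check no real-data study
can run).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifiers as clf
from . import evaluation as ev
from .expert_rule import ExpertRuleConfig, el_serag_classify
from .features import CodeDictionary, ConfigError, extract_features, read_claims, read_cohort
from .latent_class import (
    INDICATOR_COLUMNS,
    LcaPriors,
    McmcConfig,
    gibbs_sample,
    latent_reference,
    pattern_counts,
    pattern_posterior,
)
from .synthetic import SyntheticConfig, generate_cohort, write_cohort_files

logger = logging.getLogger(__name__)

CANDIDATE_VARIABLES = [
    "age",
    "sex",
    "colonoscopy",
    "polypectomy",
    "sigmoidoscopy",
    "dcbe",
    "rectal_bleeding",
    "anemia",
    "diarrhea",
    "vomiting",
    "weight_loss",
    "ibd",
    "colorectal_polyps",
    "crc",
    "large_bowel_hospitalization",
    "large_bowel_surgery",
]

FLAG_VARIABLES = CANDIDATE_VARIABLES[2:]


@dataclass
class PipelineConfig:
    """Exactly one of ``synthetic`` (generator settings) or ``inputs``
    (paths to indicator/claims/cohort files) must be set."""

    synthetic: SyntheticConfig | None = None
    inputs: dict | None = None
    priors: LcaPriors = field(default_factory=LcaPriors.default)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    dependence: bool = False
    tree: clf.TreeConfig = field(default_factory=clf.TreeConfig)
    best_subset: bool = True
    candidates: list | None = None  # default: age, sex + all 14 claims flags
    seed: int = 0

    def __post_init__(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError("set exactly one of synthetic | inputs")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "synthetic" in raw:
            kwargs["synthetic"] = SyntheticConfig.from_mapping(raw["synthetic"])
        if "inputs" in raw:
            kwargs["inputs"] = dict(raw["inputs"])
        if "priors" in raw:
            kwargs["priors"] = LcaPriors.from_mapping(raw["priors"])
        if "mcmc" in raw:
            kwargs["mcmc"] = McmcConfig.from_mapping(raw["mcmc"])
        for key in ("dependence", "best_subset", "candidates", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "tree" in raw:
            kwargs["tree"] = clf.TreeConfig(**raw["tree"])
        if seed is not None:
            kwargs["seed"] = seed
        return cls(**kwargs)

    def fingerprint(self) -> str:
        def default(o):
            if isinstance(o, (frozenset, set)):
                return sorted(o)
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        blob = json.dumps(
            {
                "synthetic": asdict(self.synthetic) if self.synthetic else None,
                "inputs": self.inputs,
                "priors": {
                    "prevalence": [self.priors.prevalence.a, self.priors.prevalence.b],
                    "sens": [[p.a, p.b] for p in self.priors.sens],
                    "spec": [[p.a, p.b] for p in self.priors.spec],
                },
                "mcmc": asdict(self.mcmc),
                "dependence": self.dependence,
                "tree": asdict(self.tree),
                "best_subset": self.best_subset,
                "candidates": self.candidates,
                "seed": self.seed,
            },
            sort_keys=True,
            default=default,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _roc_block(r: clf.RocResult) -> dict:
    return {"auc": r.auc, "ci_low": r.ci_low, "ci_high": r.ci_high}


def _accuracy_block(pred_labels, ref_labels) -> dict:
    ct = ev.confusion(pred_labels, ref_labels)
    rep = ev.accuracy_report(ct)
    return {
        "confusion": {"tp": ct.tp, "fp": ct.fp, "fn": ct.fn, "tn": ct.tn},
        **rep.as_dict(),
    }


def _kappa_block(k: ev.KappaResult) -> dict:
    return {
        "kappa": k.kappa,
        "ci_low": k.ci_low,
        "ci_high": k.ci_high,
        "observed_agreement": k.observed_agreement,
        "expected_agreement": k.expected_agreement,
    }


def run_pipeline(
    config: PipelineConfig,
    outdir=None,
    dictionary: CodeDictionary | None = None,
    expert_config: ExpertRuleConfig | None = None,
) -> dict:
    """Execute the full workflow and return the consolidated report.

    When ``outdir`` is given, per-stage artifacts (generated tables, feature
    table, posterior summary, labels) plus ``report.json`` and a plain-text
    summary are written there.  Byte-identical outputs for a fixed config.
    """
    dictionary = dictionary or CodeDictionary.default()
    expert_config = expert_config or ExpertRuleConfig.default()
    out = Path(outdir) if outdir is not None else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: data -----------------------------------------------------
    stage = "data"
    try:
        if config.synthetic is not None:
            syn = SyntheticConfig(**{**asdict(config.synthetic), "seed": config.seed})
            truth, indicators, claims = generate_cohort(syn, dictionary)
            cohort = truth
            if out:
                write_cohort_files(truth, indicators, claims, out / "data")
        else:
            indicators = pd.read_csv(config.inputs["indicators"])
            claims = read_claims(config.inputs["claims"])
            cohort = read_cohort(config.inputs["cohort"])
            truth = cohort if "latent_indication" in cohort.columns else None

        # --- stage 2: claims features -------------------------------------
        stage = "features"
        features = extract_features(claims, cohort, dictionary)
        if out:
            features.to_csv(out / "features.csv", index=False)

        # --- stage 3: latent class model -----------------------------------
        stage = "latent_class"
        counts = pattern_counts(indicators)
        draws = gibbs_sample(
            counts,
            config.priors,
            config.mcmc,
            dependence=config.dependence,
            seed=config.seed + 1,
        )
        post = pattern_posterior(draws)
        latent = latent_reference(indicators, draws)
        if out:
            draws.summary().to_csv(out / "lca_posterior_summary.csv", index=False)
            post.table.to_csv(out / "lca_pattern_posterior.csv", index=False)
            latent.to_csv(out / "latent_reference.csv", index=False)

        endo = pd.DataFrame(
            {
                "patient_id": indicators["patient_id"].to_numpy(),
                "label": indicators["endoscopist"].to_numpy(dtype=int),
            }
        )
        kappa = ev.cohens_kappa(latent, endo)

        # --- stage 4: classifiers ------------------------------------------
        stage = "classifiers"
        outcomes = {"latent": latent, "endoscopist": endo}
        feats = features.set_index("patient_id")
        report_models = {}
        tree_labels = {}
        candidates = config.candidates or CANDIDATE_VARIABLES
        for name, ref in outcomes.items():
            y = ref.set_index("patient_id").loc[feats.index, "label"].to_numpy()
            full = clf.fit_logistic(feats, y, candidates)
            full_auc = clf.auc(clf.predict_prob(full, feats), y)
            block = {
                "full_logistic": {
                    "variables": full.variables,
                    "bic": full.bic,
                    "auc": _roc_block(full_auc),
                }
            }
            if config.best_subset:
                best = clf.best_subset_by_bic(feats, y, candidates)
                best_auc = clf.auc(clf.predict_prob(best, feats), y)
                block["bic_logistic"] = {
                    "variables": best.variables,
                    "bic": best.bic,
                    "odds_ratios": {
                        v: float(np.exp(best.coefficients[v])) for v in best.variables
                    },
                    "auc": _roc_block(best_auc),
                }
            tree = clf.fit_tree(feats, y, FLAG_VARIABLES, config.tree)
            pred = pd.DataFrame(
                {"patient_id": feats.index.to_numpy(), "label": clf.tree_classify(tree, feats)}
            )
            tree_labels[name] = pred
            block["tree"] = {
                "variables": tree.variables_used(),
                "n_leaves": tree.leaves(),
                "depth": tree.depth(),
            }
            report_models[name] = block
            if out:
                (out / f"tree_{name}.json").write_text(
                    json.dumps(tree.to_dict(), indent=2, sort_keys=True)
                )

        # --- stage 5: expert rule ------------------------------------------
        stage = "expert_rule"
        expert = el_serag_classify(claims, cohort, expert_config)
        if out:
            expert.to_csv(out / "expert_labels.csv", index=False)

        # --- stage 6: evaluation -------------------------------------------
        stage = "evaluation"
        evaluation = {
            "tree_latent_vs_latent": _accuracy_block(tree_labels["latent"], latent),
            "tree_endoscopist_vs_endoscopist": _accuracy_block(
                tree_labels["endoscopist"], endo
            ),
            "el_serag_vs_latent": _accuracy_block(expert, latent),
            "el_serag_vs_endoscopist": _accuracy_block(expert, endo),
        }
        vs_truth = None
        if truth is not None:
            tr = pd.DataFrame(
                {
                    "patient_id": truth["patient_id"].to_numpy(),
                    "label": truth["latent_indication"].to_numpy(dtype=int),
                }
            )
            vs_truth = {
                "latent_reference_vs_truth": _accuracy_block(latent, tr),
                "endoscopist_vs_truth": _accuracy_block(endo, tr),
                "tree_latent_vs_truth": _accuracy_block(tree_labels["latent"], tr),
                "tree_endoscopist_vs_truth": _accuracy_block(
                    tree_labels["endoscopist"], tr
                ),
                "el_serag_vs_truth": _accuracy_block(expert, tr),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = {
        "header": {
            "seed": config.seed,
            "config_fingerprint": config.fingerprint(),
            "n_patients": int(len(cohort)),
            "dependence_model": config.dependence,
            "mcmc": asdict(config.mcmc),
            "rhat_prevalence": draws.meta["rhat_prevalence"],
        },
        "latent_class": {
            "pattern_counts": counts.as_dict(),
            "screening_count": int(latent["label"].sum()),
            "screening_fraction": float(latent["label"].mean()),
            "posterior_summary": {
                row["parameter"]: {
                    "median": row["median"],
                    "ci_2.5": row["ci_2.5"],
                    "ci_97.5": row["ci_97.5"],
                }
                for _, row in draws.summary().iterrows()
            },
            "kappa_latent_vs_endoscopist": _kappa_block(kappa),
        },
        "models": report_models,
        "evaluation": evaluation,
        "vs_truth": vs_truth,
    }
    if out:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "summary.txt").write_text(render_summary(report))
    return report


def render_summary(report: dict) -> str:
    """Human-readable digest of the consolidated report."""
    lines = []
    h = report["header"]
    lines.append(f"coloscreen pipeline report  (seed={h['seed']}, config={h['config_fingerprint']})")
    lines.append(f"patients: {h['n_patients']}   dependence model: {h['dependence_model']}")
    lc = report["latent_class"]
    lines.append(
        f"latent reference: {lc['screening_count']} screening exams "
        f"({100 * lc['screening_fraction']:.1f}%), "
        f"kappa vs endoscopist {lc['kappa_latent_vs_endoscopist']['kappa']:.3f} "
        f"({lc['kappa_latent_vs_endoscopist']['ci_low']:.3f}-"
        f"{lc['kappa_latent_vs_endoscopist']['ci_high']:.3f})"
    )
    for outcome, block in report["models"].items():
        a = block["full_logistic"]["auc"]
        line = f"[{outcome}] full logistic AUC {a['auc']:.3f} ({a['ci_low']:.3f}-{a['ci_high']:.3f})"
        if "bic_logistic" in block:
            b = block["bic_logistic"]["auc"]
            line += (
                f"; BIC-best AUC {b['auc']:.3f} ({b['ci_low']:.3f}-{b['ci_high']:.3f}) "
                f"with {len(block['bic_logistic']['variables'])} variables"
            )
        lines.append(line)
        lines.append(
            f"[{outcome}] tree: {block['tree']['n_leaves']} leaves, "
            f"variables {', '.join(block['tree']['variables']) or '(none)'}"
        )
    for name, block in report["evaluation"].items():
        s = block["sensitivity"]["value"]
        c = block["specificity"]["value"]
        p = block["ppv"]["value"]
        n = block["npv"]["value"]
        fmt = lambda v: "NA" if v is None else f"{v:.1f}"
        lines.append(
            f"{name}: sens {fmt(s)}%  spec {fmt(c)}%  PPV {fmt(p)}%  NPV {fmt(n)}%"
        )
    if report.get("vs_truth"):
        lines.append("-- scored against the true (simulated) indication --")
        for name, block in report["vs_truth"].items():
            fmt = lambda v: "NA" if v is None else f"{v:.1f}"
            lines.append(
                f"{name}: sens {fmt(block['sensitivity']['value'])}%  "
                f"spec {fmt(block['specificity']['value'])}%"
            )
    return "\n".join(lines) + "\n"
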