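"""End-to-end orchestration: configuration, seeded runs, machine-readable report.

A run executes the enabled stages in dependency order —

    simulate -> fracmetrics -> proteomics -> catalogues -> rna

— writes every stage's tables to the output directory and assembles a JSON
report of headline numbers (recoveries, enrichment factors, significant
counts, catalogue sizes, GSEA scores) plus all warnings raised along the
way.  One global seed drives everything; per-stage seeds are derived by a
stable hash of the stage name so that toggling one stage never shifts the
randomness of another.  Reports regenerated from the same configuration are
byte-identical.
"""

from __future__ import annotations

import json
import hashlib
import warnings
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalogues as cat
from . import fracmetrics as fm
from . import proteostats as ps
from . import rnastats as rs
from . import synthdata as sd

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline", "stage_seed"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "fracmetrics": True,
        "proteomics": True,
        "catalogues": True,
        "rna": True,
    },
    "simulate": {
        "plasma_volume_ml": 2.0,
        "noise_cv": 0.10,
        "crude_fractions": [5, 6],
    },
    "proteomics": {
        "s0": 0.1,
        "min_valid_fraction": 2.0 / 3.0,
        "n_permutations": 250,
        "fdr_alpha": 0.05,
    },
    "catalogues": {"alpha": 0.05},
    "rna": {
        "n_reps": 4,
        "gsea_permutations": 1000,
        "lfc_threshold": 1.0,
        "alpha": 0.05,
    },
}

_SCHEMA: dict = {
    "seed": {"type": int, "min": 0},
    "stages": {
        "simulate": {"type": bool},
        "fracmetrics": {"type": bool},
        "proteomics": {"type": bool},
        "catalogues": {"type": bool},
        "rna": {"type": bool},
    },
    "simulate": {
        "plasma_volume_ml": {"type": (int, float), "min": 1e-9},
        "noise_cv": {"type": (int, float), "min": 0.0},
        "crude_fractions": {"type": list},
    },
    "proteomics": {
        "s0": {"type": (int, float), "min": 0.0},
        "min_valid_fraction": {"type": (int, float), "min": 0.0, "max": 1.0},
        "n_permutations": {"type": int, "min": 10},
        "fdr_alpha": {"type": (int, float), "min": 1e-12, "max": 1.0 - 1e-12},
    },
    "catalogues": {"alpha": {"type": (int, float), "min": 1e-12, "max": 1.0 - 1e-12}},
    "rna": {
        "n_reps": {"type": int, "min": 2},
        "gsea_permutations": {"type": int, "min": 10},
        "lfc_threshold": {"type": (int, float), "min": 0.0},
        "alpha": {"type": (int, float), "min": 1e-12, "max": 1.0 - 1e-12},
    },
}


def load_config(path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh) or {}
    config = _merge(DEFAULT_CONFIG, {})
    errors = validate_config(loaded)
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(errors))
    return _merge(config, loaded)


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if isinstance(v, dict):
            out[k] = _merge(v, override.get(k, {}))
        else:
            out[k] = override.get(k, v)
    return out


def validate_config(config: dict) -> list[str]:
    """Schema-check a (possibly partial) configuration; returns error messages.

    Unknown keys are rejected rather than silently ignored.
    """
    errors: list[str] = []

    def check(section: dict, schema: dict, prefix: str) -> None:
        for key, value in section.items():
            if key not in schema:
                errors.append(f"{prefix}{key}: unknown key")
                continue
            rule = schema[key]
            if "type" not in rule:  # nested section
                if not isinstance(value, dict):
                    errors.append(f"{prefix}{key}: expected a mapping")
                else:
                    check(value, rule, f"{prefix}{key}.")
                continue
            expected = rule["type"]
            if isinstance(value, bool) and expected is int:
                errors.append(f"{prefix}{key}: expected integer, got boolean")
                continue
            if not isinstance(value, expected):
                errors.append(f"{prefix}{key}: expected {expected}, got {type(value).__name__}")
                continue
            if "min" in rule and isinstance(value, (int, float)) and value < rule["min"]:
                errors.append(f"{prefix}{key}: value {value} below minimum {rule['min']}")
            if "max" in rule and isinstance(value, (int, float)) and value > rule["max"]:
                errors.append(f"{prefix}{key}: value {value} above maximum {rule['max']}")

    if not isinstance(config, dict):
        return ["configuration root must be a mapping"]
    check(config, _SCHEMA, "")
    return errors


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: hashing the stage name decouples the stages."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _WarningCollector:
    def __init__(self, report: dict, stage: str):
        self.report = report
        self.stage = stage

    def __enter__(self):
        self._ctx = warnings.catch_warnings(record=True)
        self._records = self._ctx.__enter__()
        warnings.simplefilter("always")
        return self

    def __exit__(self, *exc):
        self._ctx.__exit__(*exc)
        for w in self._records:
            self.report.setdefault("warnings", []).append(f"{self.stage}: {w.message}")
        return False


def _density_window_ids(run: fm.FractionationRun, lo: float, hi: float) -> list[int]:
    dens = run.fractions["density_g_ml"]
    ids = run.fractions.loc[(dens >= lo - 1e-9) & (dens <= hi + 1e-9), "fraction_id"]
    return [int(i) for i in ids]


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the enabled stages and write outputs plus ``report.json``.

    Raises an actionable error naming the stage when an enabled stage's
    upstream output is missing (e.g. catalogues without proteomics).
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(errors))
    config = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    seed = config["seed"]
    report: dict = {"config": config, "stages": {}, "inputs": {}, "warnings": []}

    # --- dependency checks up front, fail fast -----------------------------
    deps = {
        "fracmetrics": ["simulate"],
        "proteomics": ["simulate"],
        "catalogues": ["simulate", "proteomics"],
        "rna": ["simulate"],
    }
    for stage, needed in deps.items():
        if stages.get(stage):
            for up in needed:
                if not stages.get(up):
                    raise ValueError(
                        f"stage '{stage}' is enabled but its upstream stage "
                        f"'{up}' is disabled; enable '{up}' or disable '{stage}'"
                    )

    sec_sim = odg_sim = None
    lfq = lfq_groups = annotations = None
    diff_lpp_ev = None
    crude_ids = [int(f) for f in config["simulate"]["crude_fractions"]]

    if stages.get("simulate"):
        with _WarningCollector(report, "simulate"):
            sim_seed = stage_seed(seed, "simulate")
            plasma = sd.make_default_plasma(
                sim_seed, volume_ml=config["simulate"]["plasma_volume_ml"]
            )
            column = sd.SECColumnModel(noise_cv=config["simulate"]["noise_cv"])
            sec_sim = sd.simulate_sec(plasma, column, seed=sim_seed)
            extract = sd.pool_extract(sec_sim, crude_ids)
            gradient = sd.DensityGradientModel(noise_cv=config["simulate"]["noise_cv"])
            odg_sim = sd.simulate_odg(extract, gradient, seed=sim_seed + 1)
            fm.write_run(sec_sim.run, outdir / "sec_run.tsv")
            fm.write_run(odg_sim.run, outdir / "odg_run.tsv")

            design, annotations = sd.default_proteomics_design(
                seed=stage_seed(seed, "lfq")
            )
            lfq, lfq_groups, lfq_truth = sd.simulate_lfq(design)
            lfq.to_csv(outdir / "lfq_matrix.tsv", sep="\t")
            lfq_groups.rename("group").to_csv(outdir / "lfq_groups.tsv", sep="\t")
            lfq_truth.to_csv(outdir / "lfq_truth.tsv", sep="\t")
            annotations.to_csv(outdir / "annotations.tsv", sep="\t")

            rna_design = sd.default_rna_design(
                seed=stage_seed(seed, "rna_sim"), n_reps=config["rna"]["n_reps"]
            )
            rna_counts, rna_groups, rna_annot = sd.simulate_smallrna(rna_design)
            rna_counts.to_csv(outdir / "rna_counts.tsv", sep="\t")
            rna_groups.rename("group").to_csv(outdir / "rna_groups.tsv", sep="\t")
            rna_annot.to_csv(outdir / "rna_annotation.tsv", sep="\t")
        report["inputs"]["sec_run"] = _hash_file(outdir / "sec_run.tsv")
        report["inputs"]["lfq_matrix"] = _hash_file(outdir / "lfq_matrix.tsv")
        report["inputs"]["rna_counts"] = _hash_file(outdir / "rna_counts.tsv")
        report["stages"]["simulate"] = {
            "n_sec_fractions": sec_sim.run.n_fractions,
            "n_odg_fractions": odg_sim.run.n_fractions,
            "n_lfq_features": int(lfq.shape[0]),
            "n_rna_features": int(rna_counts.shape[0]),
        }

    if stages.get("fracmetrics"):
        with _WarningCollector(report, "fracmetrics"):
            sec_run, odg_run = sec_sim.run, odg_sim.run
            ev_ids = _density_window_ids(odg_run, 1.09, 1.10)
            lpp_ids = _density_window_ids(odg_run, 1.04, 1.07)
            sec_metrics = {
                f"sec56_recovery_{a}": fm.recovery_fraction(sec_run, crude_ids, a)
                for a in ("particles", "protein", "CD9", "APOA1", "APOB")
            }
            odg_metrics = {
                "odg_ev_window_recovery_CD9": fm.recovery_fraction(odg_run, ev_ids, "CD9"),
                "odg_lpp_window_recovery_APOA1": fm.recovery_fraction(odg_run, lpp_ids, "APOA1"),
                "odg_lpp_window_recovery_APOB": fm.recovery_fraction(odg_run, lpp_ids, "APOB"),
            }
            enr = fm.compute_enrichment(sec_run, crude_ids, "particles", "protein")
            dep = fm.compute_enrichment(sec_run, crude_ids, "particles", "APOA1")
            profiles = pd.DataFrame(
                {a: fm.elution_profile(sec_run, a) for a in sec_run.analytes}
            )
            profiles.to_csv(outdir / "sec_profiles.tsv", sep="\t")
            report["stages"]["fracmetrics"] = {
                **{k: round(v, 6) for k, v in sec_metrics.items()},
                **{k: round(v, 6) for k, v in odg_metrics.items()},
                "sec56_enrichment_particles_vs_protein": round(enr.factor, 3),
                "sec56_enrichment_particles_vs_APOA1": round(dep.factor, 3),
            }

    if stages.get("proteomics"):
        with _WarningCollector(report, "proteomics"):
            pcfg = ps.TestConfig(
                s0=config["proteomics"]["s0"],
                min_valid_fraction=config["proteomics"]["min_valid_fraction"],
                n_permutations=config["proteomics"]["n_permutations"],
                fdr_alpha=config["proteomics"]["fdr_alpha"],
                seed=stage_seed(seed, "proteomics"),
            )
            filtered = ps.filter_valid(lfq, lfq_groups, pcfg)
            imputed = ps.impute_missing(filtered, pcfg)
            diff_lpp_ev = ps.permutation_fdr(imputed, lfq_groups, "LPP", "EV", pcfg)
            diff_lpp_ev.to_csv(outdir / "diff_lpp_vs_ev.tsv", sep="\t")
            corr = ps.correlation_summary(imputed, lfq_groups)
            _, evr = ps.pca_scores(imputed)
            report["stages"]["proteomics"] = {
                "n_tested": int(len(diff_lpp_ev)),
                "n_significant": int(diff_lpp_ev["significant"].sum()),
                "pc1_variance_pct": round(float(evr[0]) * 100, 2),
                "median_within_group_r": {
                    g: round(v[0], 4) for g, v in corr.within.items()
                },
            }

    if stages.get("catalogues"):
        with _WarningCollector(report, "catalogues"):
            crude_cols = lfq_groups.index[lfq_groups == "crude"]
            present = cat.crude_presence(lfq[crude_cols])
            ev_cols = lfq_groups.index[lfq_groups == "EV"]
            ev_valid = lfq[ev_cols].notna().sum(axis=1) / len(ev_cols)
            alpha = config["catalogues"]["alpha"]
            catalogue = cat.build_catalogue(
                present, diff_lpp_ev, annotations=annotations, alpha=alpha,
                ev_valid_fraction=ev_valid,
            )
            catalogue.to_csv(outdir / "catalogue.tsv", sep="\t")
            corona_ids = catalogue.index[catalogue["category"] == "corona_candidate"]
            corr_result = None
            if len(corona_ids) >= 5:
                lfq_cfg = ps.TestConfig(seed=stage_seed(seed, "proteomics"))
                ev_means = ps.impute_missing(
                    ps.filter_valid(lfq, lfq_groups, lfq_cfg), lfq_cfg
                )[ev_cols].mean(axis=1)
                try:
                    rho, p = cat.corona_concentration_correlation(
                        ev_means.reindex(corona_ids), annotations
                    )
                    corr_result = {"rho": round(rho, 4), "p": round(p, 4)}
                except ValueError:
                    corr_result = None
            report["stages"]["catalogues"] = {
                "n_non_ev_associated": int((catalogue["category"] == "non_EV_associated").sum()),
                "n_corona_candidates": int(len(corona_ids)),
                "concentration_correlation": corr_result,
            }

    if stages.get("rna"):
        with _WarningCollector(report, "rna"):
            rcfg = config["rna"]
            filtered_counts = rs.filter_features(rna_counts, rna_groups)
            de = rs.nb_wald_test(
                filtered_counts, rna_groups, "plasma", "EV",
                lfc_threshold=rcfg["lfc_threshold"], alpha=rcfg["alpha"],
            )
            de.to_csv(outdir / "rna_de.tsv", sep="\t")
            comp = rs.biotype_composition(filtered_counts, rna_annot, rna_groups)
            codon = rs.codon_usage_profile(
                filtered_counts, rna_annot, rna_groups, "EV", "plasma"
            )
            codon.to_csv(outdir / "codon_usage.tsv", sep="\t")
            ranked = de.sort_values("log2fc", ascending=False).index.tolist()
            gsea = {}
            for name, members in sd.default_gene_sets().items():
                try:
                    res = rs.gsea_classic(
                        ranked, members, n_permutations=rcfg["gsea_permutations"],
                        seed=stage_seed(seed, f"gsea_{name}"), set_name=name,
                    )
                    gsea[name] = {"es": round(res.es, 4), "nes": round(res.nes, 4),
                                  "p": round(res.p, 4)}
                except ValueError:
                    gsea[name] = None
            n_fc = codon["fold_change"].dropna()
            report["stages"]["rna"] = {
                "n_features_kept": int(len(filtered_counts)),
                "n_de": int(de["de"].sum()),
                "biotype_proportions_EV": {
                    b: round(float(v), 4) for b, v in comp["EV"].items()
                } if "EV" in comp else {},
                "n_isotypes": int(len(codon)),
                "n_isotypes_fc_gt1_in_EV": int((n_fc > 1).sum()),
                "gsea": gsea,
            }

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True,
                                      default=_json_default) + "\n")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
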