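"""End-to-end orchestration: config in, tidy CSV results + manifest out.

A pipeline run reads the per-class glycomics tables, derives trait matrices
and their cross-class integration, explores them by unit-variance PCA and
z-score group (radar) profiles, correlates traits with GST and TF expression,
optionally bridges to a second cohort with GST×TF correlation matrices and
the RV2 coefficient, and screens genes across FAB classes with ANOVA + Tukey.
Every artifact is written as CSV (or JSON for scalars) plus a deterministic
run manifest; re-running with the same config and seed reproduces every
output byte for byte.
"""

from __future__ import annotations

import json
import logging
import traceback
from pathlib import Path

import pandas as pd

from . import correlation, group_stats, multivariate, omics_io, trait_engine

__all__ = ["STAGES", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("traits", "pca", "correlate", "rv2", "fab_screen")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and original cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, float_format="%.10g", **kwargs)


def run_pipeline(config, output_dir: str | Path | None = None) -> dict:
    """Execute the configured stages; return a dict of result objects.

    ``config`` is a YAML path or a mapping with keys ``inputs`` (paths for
    ``glycomics`` per class, ``expression``, optional ``fab_labels`` and
    ``second_expression``), ``stages``, ``seed``, ``output_dir`` and optional
    ``gene_panels``, ``trait_rules``, ``pca``, ``radar_groups``.
    """
    cfg = _load_config(config)
    stages = tuple(cfg.get("stages", STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid: {list(STAGES)}")
    out = Path(output_dir or cfg.get("output_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    inputs = cfg.get("inputs", {})
    manifest: dict = {
        "seed": seed,
        "stages": list(stages),
        "inputs": {k: str(v) for k, v in _flatten(inputs).items()},
        "warnings": [],
        "outputs": [],
    }
    results: dict = {}
    current_stage = "load"
    try:
        # ---------------- load ----------------
        fab = None
        if inputs.get("fab_labels"):
            fab = omics_io.read_fab_labels(inputs["fab_labels"])
        panels_cfg = _gene_panels(cfg)
        rules = (
            omics_io.read_trait_rules(cfg["trait_rules"])
            if cfg.get("trait_rules")
            else trait_engine.default_rules()
        )
        glyco = {
            cls: omics_io.read_glycomics_table(path, cls, fab_labels=fab)
            for cls, path in sorted(inputs.get("glycomics", {}).items())
        }
        expr = None
        if inputs.get("expression"):
            expr = omics_io.read_expression_matrix(
                inputs["expression"], panels=panels_cfg, fab_labels=fab
            )
        results["expression"] = expr

        # ---------------- traits ----------------
        if "traits" in stages:
            current_stage = "traits"
            if not glyco:
                raise ValueError("traits stage requires glycomics inputs")
            per_class = {
                cls: trait_engine.compute_trait_matrix(panel, rules)
                for cls, panel in glyco.items()
            }
            integrated = trait_engine.integrate_traits(list(per_class.values()))
            results["traits"] = per_class
            results["integrated"] = integrated
            for cls, tm in per_class.items():
                path = out / f"traits_{cls}.csv"
                _csv(tm.values, path, index_label="sample")
                manifest["outputs"].append(path.name)
            _csv(integrated.values, out / "traits_integrated.csv", index_label="sample")
            manifest["outputs"].append("traits_integrated.csv")

        # ---------------- pca + radar ----------------
        if "pca" in stages:
            current_stage = "pca"
            blocks = list(results["traits"].values())
            combined = multivariate.balance_features(
                blocks, policy=cfg.get("pca", {}).get("policy", "min_block")
            )
            pca = multivariate.pca_unit_variance(
                combined, cfg.get("pca", {}).get("n_components")
            )
            results["pca"] = pca
            _csv(pca.scores, out / "pca_scores.csv", index_label="sample")
            _csv(pca.loadings, out / "pca_loadings.csv", index_label="feature")
            evr = pd.DataFrame(
                {
                    "component": pca.components,
                    "explained_variance_ratio": pca.explained_variance_ratio,
                }
            )
            _csv(evr, out / "pca_explained_variance.csv", index=False)
            z = multivariate.z_transform(combined)
            results["z_scores"] = z
            _csv(z, out / "z_scores.csv", index_label="sample")
            manifest["outputs"] += [
                "pca_scores.csv",
                "pca_loadings.csv",
                "pca_explained_variance.csv",
                "z_scores.csv",
            ]
            if fab is not None:
                groups = cfg.get("radar_groups")
                profile = multivariate.group_profile(z, fab, groups)
                results["radar"] = profile
                _csv(profile, out / "radar_profiles.csv")
                manifest["outputs"].append("radar_profiles.csv")

        # ---------------- correlations ----------------
        if "correlate" in stages:
            current_stage = "correlate"
            if expr is None:
                raise ValueError("correlate stage requires an expression matrix")
            gst = _panel_frame(expr, "GST")
            tf = _panel_frame(expr, "TF")
            integrated = results["integrated"]
            pairs = {
                "corr_traits_gst": correlation.correlate_blocks(integrated, gst),
                "corr_traits_tf": correlation.correlate_blocks(integrated, tf),
                "corr_gst_tf": correlation.correlate_blocks(gst, tf),
            }
            for name, res in pairs.items():
                results[name] = res
                _csv(res.to_long(), out / f"{name}.csv", index=False)
                manifest["outputs"].append(f"{name}.csv")

        # ---------------- rv2 bridge ----------------
        if "rv2" in stages:
            current_stage = "rv2"
            if not inputs.get("second_expression"):
                raise ValueError("rv2 stage requires inputs.second_expression")
            expr2 = omics_io.read_expression_matrix(
                inputs["second_expression"], panels=panels_cfg
            )
            gst1, tf1 = _panel_frame(expr, "GST"), _panel_frame(expr, "TF")
            gst2, tf2 = _panel_frame(expr2, "GST"), _panel_frame(expr2, "TF")
            res1 = correlation.correlate_blocks(gst1, tf1)
            res2 = correlation.correlate_blocks(gst2, tf2)
            _csv(res2.to_long(), out / "corr_gst_tf_second.csv", index=False)
            A, B = correlation.align_by_rows(res1.rho, res2.rho)
            rv = correlation.rv2_permutation_test(
                A, B, n_perm=int(cfg.get("rv2_permutations", 999)), seed=seed
            )
            results["rv2"] = rv
            with open(out / "rv2.json", "w") as fh:
                json.dump(
                    {
                        "coefficient": rv.coefficient,
                        "p_value": rv.p_value,
                        "n_permutations": rv.n_permutations,
                        "seed": rv.seed,
                        "n_shared_genes": int(A.shape[0]),
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
            manifest["outputs"] += ["corr_gst_tf_second.csv", "rv2.json"]

        # ---------------- FAB screen ----------------
        if "fab_screen" in stages:
            current_stage = "fab_screen"
            if expr is None or expr.fab_labels is None:
                raise ValueError("fab_screen stage requires expression + FAB labels")
            panel_genes = [
                g for g in expr.genes if expr.panel_tags.get(g) in ("GST", "TF")
            ]
            screen = group_stats.fab_screen(
                expr, omics_io.GenePanel("GST+TF", panel_genes)
            )
            results["fab_screen"] = screen
            _csv(screen["pairs"], out / "fab_screen_pairs.csv", index=False)
            _csv(screen["anova"], out / "fab_screen_anova.csv", index=False)
            manifest["fab_excluded_groups"] = screen["excluded_groups"]
            manifest["fab_genes_not_found"] = screen["not_found"]
            manifest["outputs"] += ["fab_screen_pairs.csv", "fab_screen_anova.csv"]

    except Exception as exc:
        (out / "FAILED").write_text(
            f"stage: {current_stage}\n{exc}\n\n{traceback.format_exc()}"
        )
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(current_stage, exc) from exc

    omics_io.write_manifest(manifest, out / "manifest.json")
    results["manifest"] = manifest
    results["output_dir"] = out
    return results


def _flatten(d: dict, prefix: str = "") -> dict:
    flat = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            flat.update(_flatten(v, f"{key}."))
        else:
            flat[key] = v
    return flat


def _gene_panels(cfg: dict):
    spec = cfg.get("gene_panels")
    if spec is None:
        from .synthetic_data import DEFAULT_GST_PANEL, DEFAULT_TF_PANEL

        return [
            omics_io.GenePanel("GST", list(DEFAULT_GST_PANEL)),
            omics_io.GenePanel("TF", list(DEFAULT_TF_PANEL)),
        ]
    if isinstance(spec, (str, Path)):
        return omics_io.read_gene_panels(spec)
    return [omics_io.GenePanel(name, list(genes)) for name, genes in spec.items()]


def _panel_frame(expr, panel_name: str) -> pd.DataFrame:
    """Samples × genes frame of the genes tagged with ``panel_name``."""
    genes = [g for g in expr.genes if expr.panel_tags.get(g) == panel_name]
    if not genes:
        raise ValueError(f"no genes tagged {panel_name!r} in expression matrix")
    return expr.values.loc[genes].T
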