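"""End-to-end orchestration: simulate/load -> spectra -> tests -> pGLS -> report.

A run either simulates a data set (via :mod:`radmut.simulate`) or loads a
tree, a covariate table and a site-allele table from disk, then produces a
deterministic directory of TSV reports:

- ``spectra.tsv``           pooled mutational spectrum per species x filter
- ``contrasts.tsv``         per-pair log-ratio contrasts of pooled classes
- ``ordered_tests.tsv``     ordered chi-square forward selection + Holm
- ``pgls_rates.tsv``        rate regressions (dS/ra vs radioactivity proxies)
- ``pgls_spectrum.tsv``     spectrum-proportion regressions, Holm-corrected
- ``diagnostics.tsv``       Shapiro p and jackknife influence summaries
- ``manifest.json``         seed, config hash, package and library versions
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import ordered_tests, pgls, simulate, spectrum

logger = logging.getLogger("radmut")

RATE_RESPONSES = ("ds_ra", "ds_ra_mito")
PREDICTORS = ("log_alpha", "log_rd", "lambda15")
#: predictors whose analyses honour the tip exclusion list (site-specific
#: measurements that can be perturbed locally, unlike the regional lambda15)
SITE_SPECIFIC_PREDICTORS = ("log_alpha", "log_rd")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of the simulation block and the input-path block must be
    active.  ``holm_k`` defaults to 18: six pooled classes times three
    radioactivity proxies in the spectrum-regression family.
    """

    simulation: simulate.SimulationConfig | None = None
    tree_path: str | None = None
    covariates_path: str | None = None
    sites_path: str | None = None
    position_filters: tuple = ("all", "third")
    yates: bool = False
    log_transform: str = "auto"        # auto | always | never (responses)
    models: tuple = ("brownian",)
    holm_k: int = 18
    cox_snell_n_policy: str = "default"  # rows for rates, pair count for spectra
    exclude_tips: tuple = ()
    jackknife: bool = True
    outdir: str = "radmut_run"
    seed: int = 0

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_paths = any([self.tree_path, self.covariates_path, self.sites_path])
        if has_sim == has_paths:
            raise PipelineError(
                "config: exactly one of the simulation block and input paths "
                "must be active"
            )
        if has_paths and not all(
            [self.tree_path, self.covariates_path, self.sites_path]
        ):
            raise PipelineError(
                "config: tree_path, covariates_path and sites_path are all required"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = simulate.SimulationConfig(**sim)
        for key in ("position_filters", "models", "exclude_tips"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)

    def content_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Input loading and validation
# ---------------------------------------------------------------------------

@dataclass
class Finding:
    level: str   # "fatal" | "warning"
    message: str


@dataclass
class ValidationReport:
    findings: list = field(default_factory=list)

    def add(self, level: str, message: str) -> None:
        self.findings.append(Finding(level, message))

    @property
    def fatal(self) -> list:
        return [f for f in self.findings if f.level == "fatal"]

    @property
    def warnings(self) -> list:
        return [f for f in self.findings if f.level == "warning"]

    @property
    def exit_code(self) -> int:
        if self.fatal:
            return 2
        return 1 if self.warnings else 0


def validate_inputs(tree_path, covariates_path, sites_path) -> ValidationReport:
    """Structured validation of an input triplet; never raises."""
    report = ValidationReport()
    tree = None
    try:
        tree = pgls.parse_tree(
            pathlib.Path(tree_path).read_text(), check_ultrametric=False
        )
    except (OSError, pgls.TreeError) as exc:
        report.add("fatal", f"tree: {exc}")
    if tree is not None:
        spread = pgls.ultrametricity_spread(tree)
        depth = pgls.tree_depth(tree)
        if depth > 0 and spread > 1e-6 * depth:
            report.add(
                "fatal",
                f"tree: not ultrametric (root-to-tip depth spread {spread:g})",
            )
    cov = None
    try:
        cov = pd.read_csv(covariates_path, sep="\t")
        if "tip" not in cov.columns:
            report.add("fatal", "covariates: missing 'tip' column")
            cov = None
    except OSError as exc:
        report.add("fatal", f"covariates: {exc}")
    if tree is not None and cov is not None:
        tips = set(pgls.tip_labels(tree))
        table_tips = set(cov["tip"].astype(str))
        for tip in sorted(table_tips - tips):
            report.add("fatal", f"covariates: tip {tip!r} not in tree")
        for tip in sorted(tips - table_tips):
            report.add("warning", f"tree tip {tip!r} has no covariate row")
        try:
            simulate.pairs_from_labels(sorted(tips))
        except simulate.ConfigError as exc:
            report.add("warning", f"pair structure: {exc}")
        if "lambda15" in cov.columns:
            bad = cov[(cov["lambda15"] < 0) | (cov["lambda15"] > 1)]
            for tip in bad["tip"]:
                report.add("fatal", f"covariates: lambda15 outside [0,1] for {tip!r}")
    try:
        spectrum.read_site_allele_table(sites_path)
    except (OSError, spectrum.SpectrumError) as exc:
        report.add("fatal", f"sites: {exc}")
    return report


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim_cfg = config.simulation
        if sim_cfg.seed != config.seed:
            sim_cfg = simulate.SimulationConfig(**{**asdict(sim_cfg), "seed": config.seed})
        data = simulate.simulate_dataset(sim_cfg)
        return data.tree, data.covariates, data.sites
    tree = pgls.parse_tree(pathlib.Path(config.tree_path).read_text())
    cov = pd.read_csv(config.covariates_path, sep="\t").set_index("tip")
    sites = spectrum.read_site_allele_table(config.sites_path)
    return tree, cov, sites


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _maybe_log(series: pd.Series, rule: str) -> tuple[pd.Series, bool]:
    """Apply the response log-transform rule (Shapiro-based when 'auto')."""
    if rule == "never":
        return series, False
    if rule == "always":
        return np.log(series), True
    p_raw = stats.shapiro(series.to_numpy()).pvalue
    if p_raw < 0.05 and (series > 0).all():
        return np.log(series), True
    return series, False


def _spectrum_stage(sites, pairs, covariates, config):
    spectra_rows = []
    contrasts = []
    class_counts = {}       # (species, filter) -> pooled count vector
    proportions = {}        # (species, filter) -> pooled proportion vector
    for pair_id, (tip_a, tip_b) in enumerate(pairs, start=1):
        for filt in config.position_filters:
            result = spectrum.pair_spectra(sites, tip_a, tip_b, position_filter=filt)
            for sp, (counts, spec) in result.items():
                class_counts[(sp, filt)] = spectrum.pooled_counts(counts)
                proportions[(sp, filt)] = spec.p_pooled
                spectra_rows.append(
                    {"species": sp, "pair_id": f"pair{pair_id:02d}",
                     "position_filter": filt}
                    | dict(zip(spectrum.POOLED_CLASSES, spec.p_pooled))
                )
            if filt == "all":
                reg = covariates.loc[[tip_a, tip_b], "regime"]
                high = reg.index[reg == "high"]
                low = reg.index[reg == "low"]
                if len(high) == 1 and len(low) == 1:
                    delta = {
                        "lambda15": float(
                            covariates.loc[high[0], "lambda15"]
                            - covariates.loc[low[0], "lambda15"]
                        )
                    }
                    contrasts.append(
                        spectrum.pair_contrast(
                            result[high[0]][1],
                            result[low[0]][1],
                            pair_id=f"pair{pair_id:02d}",
                            delta_covariate=delta,
                        )
                    )
    return pd.DataFrame(spectra_rows), contrasts, class_counts, proportions


def _ordered_stage(class_counts, covariates, config) -> pd.DataFrame:
    frames = []
    for filt in config.position_filters:
        by_regime = {"low": np.zeros(6), "high": np.zeros(6)}
        for (sp, f), vec in class_counts.items():
            if f == filt and sp in covariates.index:
                by_regime[covariates.loc[sp, "regime"]] += vec
        result = ordered_tests.ordered_forward(
            by_regime["low"], by_regime["high"],
            classes=list(spectrum.POOLED_CLASSES), yates=config.yates,
        )
        for msg in result.warnings:
            logger.warning("ordered test (%s positions): %s", filt, msg)
        frame = result.as_frame()
        frame.insert(0, "position_filter", filt)
        frame["holm_adjusted_p"] = ordered_tests.holm_adjust(
            np.nan_to_num(frame["ordered_p"].to_numpy(), nan=1.0),
            max(config.holm_k, len(frame)),
        )
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _rate_pgls_stage(tree, covariates, config) -> tuple[pd.DataFrame, pd.DataFrame]:
    table = covariates.copy()
    table["log_alpha"] = np.log(table["alpha_radio"])
    table["log_rd"] = np.log(table["received_dose"])
    rows = []
    diag_rows = []
    for response in RATE_RESPONSES:
        if response not in table.columns:
            continue
        for predictor in PREDICTORS:
            fit_table = table
            if predictor in SITE_SPECIFIC_PREDICTORS and config.exclude_tips:
                fit_table = table.drop(
                    index=[t for t in config.exclude_tips if t in table.index]
                )
            y, logged = _maybe_log(fit_table[response], config.log_transform)
            fit_table = fit_table.assign(_response=y)
            for model in config.models:
                parameter = _default_parameter(model)
                rec = pgls.pgls_lrt(
                    fit_table, tree, "_response", predictor,
                    model=model, parameter=parameter,
                )
                rec["response"] = response + ("_log" if logged else "")
                rows.append(rec)
                if model == "brownian":
                    diag_rows.append(
                        _diagnose(fit_table, tree, "_response", predictor,
                                  response, config)
                    )
    return pd.DataFrame(rows), pd.DataFrame(diag_rows)


def _default_parameter(model: str):
    return {"brownian": None, "pagel": 0.5, "martins": 1.0, "blomberg": 0.5}[model]


def _diagnose(fit_table, tree, response, predictor, label, config) -> dict:
    labels = [str(t) for t in fit_table.index]
    extra = set(pgls.tip_labels(tree)) - set(labels)
    work = pgls.prune_tips(tree, sorted(extra)) if extra else tree
    vcv = pgls.brownian_vcv(work, labels=labels)
    fit = pgls.fit_gls(fit_table, response, [predictor], vcv)
    diag = pgls.residual_diagnostics(fit, vcv)
    rec = {"response": label, "predictor": predictor,
           "shapiro_p": diag["shapiro_p"]}
    if config.jackknife and len(fit_table) >= 4:
        jk = pgls.jackknife_fits(fit_table, tree, response, predictor)
        rec["jackknife_sign_changes"] = int(jk["sign_change"].sum())
        rec["jackknife_significance_changes"] = int(jk["significance_change"].sum())
    return rec


def _spectrum_pgls_stage(tree, covariates, proportions, pairs, config) -> pd.DataFrame:
    pair_species = [tip for pair in pairs for tip in pair]
    table = covariates.loc[[t for t in covariates.index if t in pair_species]].copy()
    table["log_alpha"] = np.log(table["alpha_radio"])
    table["log_rd"] = np.log(table["received_dose"])
    n_pair_species = len(table)
    rows = []
    for ci, cls in enumerate(spectrum.POOLED_CLASSES):
        table[cls] = [proportions.get((sp, "all"), [np.nan] * 6)[ci] for sp in table.index]
        for predictor in PREDICTORS:
            fit_table = table
            if predictor in SITE_SPECIFIC_PREDICTORS and config.exclude_tips:
                fit_table = table.drop(
                    index=[t for t in config.exclude_tips if t in table.index]
                )
            n_r2 = (
                None if config.cox_snell_n_policy == "rows" else n_pair_species
            )
            rec = pgls.pgls_lrt(
                fit_table, tree, cls, predictor, n_for_r2=n_r2,
            )
            rec["n_fitted"] = len(fit_table)
            rows.append(rec)
    frame = pd.DataFrame(rows)
    frame["holm_adjusted_p"] = ordered_tests.holm_adjust(
        frame["p_value"].to_numpy(), max(config.holm_k, len(frame))
    )
    return frame


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report directory.

    Returns the manifest (also written as ``manifest.json``).  Any stage
    failure is re-raised as :class:`PipelineError` naming the stage.
    """
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info(
        "flags: position_filters=%s yates=%s log_transform=%s models=%s "
        "holm_k=%d cox_snell_n_policy=%s exclude_tips=%s seed=%d",
        config.position_filters, config.yates, config.log_transform,
        config.models, config.holm_k, config.cox_snell_n_policy,
        config.exclude_tips, config.seed,
    )
    outputs = {}
    try:
        stage = "load-inputs"
        tree, covariates, sites = _load_inputs(config)
        pairs = simulate.pairs_from_labels(pgls.tip_labels(tree))

        stage = "spectra"
        spectra_df, contrasts, class_counts, proportions = _spectrum_stage(
            sites, pairs, covariates, config
        )
        spectra_df.to_csv(out / "spectra.tsv", sep="\t", index=False)
        outputs["spectra"] = "spectra.tsv"
        spectrum.contrast_table(contrasts).to_csv(
            out / "contrasts.tsv", sep="\t", index=False
        )
        outputs["contrasts"] = "contrasts.tsv"

        stage = "ordered-tests"
        ordered_df = _ordered_stage(class_counts, covariates, config)
        ordered_df.to_csv(out / "ordered_tests.tsv", sep="\t", index=False)
        outputs["ordered_tests"] = "ordered_tests.tsv"

        stage = "pgls-rates"
        rates_df, diagnostics_df = _rate_pgls_stage(tree, covariates, config)
        rates_df.to_csv(out / "pgls_rates.tsv", sep="\t", index=False)
        outputs["pgls_rates"] = "pgls_rates.tsv"
        diagnostics_df.to_csv(out / "diagnostics.tsv", sep="\t", index=False)
        outputs["diagnostics"] = "diagnostics.tsv"

        stage = "pgls-spectrum"
        spec_pgls_df = _spectrum_pgls_stage(tree, covariates, proportions, pairs, config)
        spec_pgls_df.to_csv(out / "pgls_spectrum.tsv", sep="\t", index=False)
        outputs["pgls_spectrum"] = "pgls_spectrum.tsv"
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    import dendropy
    import scipy

    manifest = {
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "outputs": outputs,
        "n_tips": len(pgls.tip_labels(tree)),
        "n_pairs": len(pairs),
        "versions": {
            "radmut": _package_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "dendropy": dendropy.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("radmut")
    except PackageNotFoundError:
        return "unknown"
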