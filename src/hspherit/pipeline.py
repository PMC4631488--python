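"""Study workflow orchestration.

Fits the per-age models (S-m: additive effect only; SO-m: sampling order
added as a fixed effect) and the combined-years models (Model 1: sampling
order nested in year as fixed; Model 2: exact age as covariate), screens
random effects by likelihood-ratio tests, derives the genetic-parameter
report rows, and writes the publication-style tables with a run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genetic_parameters import (
    GeneticParameters,
    parameter_table,
    predicted_response,
    summarize_fit,
)
from .mixed_model import (
    MixedModelSpec,
    ModelFit,
    ModelSpecError,
    RandomTerm,
    loglik_ratio_test,
    reml_fit,
)
from .pedigree import Pedigree, read_pedigree
from .synthetic_data import (
    SimulationConfig,
    SyntheticDataset,
    simulate_dataset,
    write_dataset,
)

__all__ = [
    "PER_AGE_MODELS",
    "COMBINED_MODELS",
    "run_per_age",
    "run_combined",
    "run_random_effect_screen",
    "reproduce_tables",
    "load_model_config",
    "spec_from_config",
    "RunManifest",
]

PER_AGE_MODELS = ("S-m", "SO-m")
COMBINED_MODELS = ("model1", "model2")
AGE_CLASS = {1: "young_adults", 2: "near_harvest_adults"}


def _additive_term() -> RandomTerm:
    return RandomTerm(name="animal_additive", column="animal", structure="additive")


def _family_term() -> RandomTerm:
    return RandomTerm(
        name="family", column="family", structure="identity", role="common_env"
    )


def _pe_term() -> RandomTerm:
    return RandomTerm(
        name="pe", column="animal", structure="identity", role="permanent_env"
    )


def _filter(phenotypes: pd.DataFrame, fraction: str, year: int | None) -> pd.DataFrame:
    df = phenotypes[phenotypes["fraction"] == fraction]
    if year is not None:
        df = df[df["year"] == year]
    if df.empty:
        raise ModelSpecError(
            f"empty stratum: fraction={fraction!r}, year={year!r}"
        )
    return df


def run_per_age(
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    *,
    fraction: str,
    year: int,
    model: str = "S-m",
    include_family: bool = False,
) -> tuple[ModelFit, GeneticParameters]:
    """Fit one age class with the simple (S-m) or order-adjusted (SO-m) model."""
    if model not in PER_AGE_MODELS:
        raise ModelSpecError(f"per-age model must be one of {PER_AGE_MODELS}")
    df = _filter(phenotypes, fraction, year)
    fixed: tuple[str, ...] = ()
    if model == "SO-m":
        if "sampling_order" not in df.columns:
            raise ModelSpecError(
                "SO-m requires a 'sampling_order' column in the phenotype table"
            )
        fixed = ("sampling_order",)
    random_terms = [_additive_term()]
    if include_family:
        random_terms.append(_family_term())
    spec = MixedModelSpec(
        response="hsp70",
        fixed_factors=fixed,
        random_terms=tuple(random_terms),
        pedigree=pedigree,
    )
    fit = reml_fit(spec, df)
    params = summarize_fit(
        fit,
        trait=f"{fraction} HSP70",
        stratum=AGE_CLASS.get(year, str(year)),
        model=model,
    )
    return fit, params


def run_combined(
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    *,
    fraction: str,
    model: str = "model1",
    include_pe: bool = True,
) -> tuple[ModelFit, GeneticParameters]:
    """Fit both years jointly; reports repeatability alongside h2.

    Model 1 fits sampling order nested in measurement year as a fixed
    factor; Model 2 fits exact age at measurement as a covariate.  The
    permanent-environment term (identity covariance on animal) is included
    by default so repeated records within an animal may covary beyond the
    additive relationship.
    """
    if model not in COMBINED_MODELS:
        raise ModelSpecError(f"combined model must be one of {COMBINED_MODELS}")
    df = _filter(phenotypes, fraction, None)
    if df["year"].nunique() < 2:
        raise ModelSpecError("combined models require records from both years")
    if model == "model1":
        fixed, covs = ("sampling_order(year)",), ()
    else:
        if "age" not in df.columns:
            raise ModelSpecError("model2 requires an 'age' column")
        fixed, covs = (), ("age",)
    random_terms = [_additive_term()]
    if include_pe:
        random_terms.append(_pe_term())
    spec = MixedModelSpec(
        response="hsp70",
        fixed_factors=fixed,
        covariates=covs,
        random_terms=tuple(random_terms),
        pedigree=pedigree,
    )
    fit = reml_fit(spec, df)
    params = summarize_fit(
        fit,
        trait=f"{fraction} HSP70",
        stratum="combined",
        model=model,
        include_repeatability=True,
    )
    return fit, params


def run_random_effect_screen(
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    *,
    fraction: str,
    year: int | None = None,
    fixed_factors: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Model-reduction screen: LRTs for the family term and the additive term.

    Fits additive+family, additive-only, and residual-only models on the same
    rows and reports both boundary likelihood-ratio tests (the family/common
    environment effect, and the additive effect = h2 significance).
    """
    df = _filter(phenotypes, fraction, year)
    base = dict(response="hsp70", fixed_factors=fixed_factors, pedigree=pedigree)
    spec_full = MixedModelSpec(
        random_terms=(_additive_term(), _family_term()), **base
    )
    spec_add = MixedModelSpec(random_terms=(_additive_term(),), **base)
    spec_null = MixedModelSpec(random_terms=(), **base)
    fit_full = reml_fit(spec_full, df)
    fit_add = reml_fit(spec_add, df)
    fit_null = reml_fit(spec_null, df)
    lrt_family = loglik_ratio_test(fit_full, fit_add)
    lrt_additive = loglik_ratio_test(fit_add, fit_null)
    return pd.DataFrame(
        [
            {
                "fraction": fraction,
                "year": year if year is not None else "combined",
                "term": "family",
                "statistic": lrt_family.statistic,
                "df": lrt_family.df,
                "p": lrt_family.p_value,
                "variance": fit_full.components.estimates["family"],
            },
            {
                "fraction": fraction,
                "year": year if year is not None else "combined",
                "term": "additive",
                "statistic": lrt_additive.statistic,
                "df": lrt_additive.df,
                "p": lrt_additive.p_value,
                "variance": fit_add.components.V_A,
            },
        ]
    )


@dataclass
class RunManifest:
    """Provenance for one pipeline run; reruns with identical inputs are
    byte-identical in the machine-readable outputs."""

    seed: int | None
    config: dict
    version: str
    input_hashes: dict = field(default_factory=dict)
    convergence: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def reproduce_tables(
    seed: int,
    outdir: str | Path,
    *,
    config: SimulationConfig | None = None,
    selected_proportion: float = 0.05,
    include_pe: bool = True,
    dataset: SyntheticDataset | None = None,
) -> RunManifest:
    """Full chain on a seeded synthetic dataset.

    Simulates the nested half-sib study, fits the four per-age models and
    the four combined fits (two models x two fractions), and writes
    table1.tsv, table2.tsv, selection_response.tsv, screen.tsv plus a
    manifest.  Raises on any non-convergence.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or SimulationConfig()
    if dataset is None:
        dataset = simulate_dataset(config, seed=seed)
    input_hashes = write_dataset(dataset, outdir / "data")

    manifest = RunManifest(
        seed=seed,
        config=asdict(config),
        version=__version__,
        input_hashes=input_hashes,
    )

    t1_rows: list[GeneticParameters] = []
    t2_rows: list[GeneticParameters] = []
    sel_rows = []
    screens = []
    for fraction in config.fractions:
        for year, model in ((1, "S-m"), (2, "SO-m")):
            fit, params = run_per_age(
                dataset.pedigree,
                dataset.phenotypes,
                fraction=fraction,
                year=year,
                model=model,
            )
            manifest.convergence[f"{fraction}/year{year}/{model}"] = {
                "converged": fit.converged,
                "iterations": fit.n_iter,
                "loglik": fit.loglik,
            }
            t1_rows.append(params)
            scen = predicted_response(
                selected_proportion,
                params.h2,
                np.sqrt(params.V_P),
                params.mean,
            )
            sel_rows.append(
                {
                    "trait": params.trait,
                    "stratum": params.stratum,
                    "proportion_selected": scen.proportion,
                    "intensity": scen.intensity,
                    "h2": scen.h2,
                    "sigma_P": scen.sigma_P,
                    "response": scen.response,
                    "response_percent": scen.response_percent,
                }
            )
        for model in COMBINED_MODELS:
            fit, params = run_combined(
                dataset.pedigree,
                dataset.phenotypes,
                fraction=fraction,
                model=model,
                include_pe=include_pe,
            )
            manifest.convergence[f"{fraction}/combined/{model}"] = {
                "converged": fit.converged,
                "iterations": fit.n_iter,
                "loglik": fit.loglik,
            }
            t2_rows.append(params)
        screens.append(
            run_random_effect_screen(
                dataset.pedigree, dataset.phenotypes, fraction=fraction, year=1
            )
        )

    files = {
        "table1.tsv": parameter_table(t1_rows),
        "table2.tsv": parameter_table(t2_rows),
        "selection_response.tsv": pd.DataFrame(sel_rows),
        "screen.tsv": pd.concat(screens, ignore_index=True),
    }
    for name, frame in files.items():
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest.outputs.append({"file": name, "sha256": _sha256(path)})
    manifest.write(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# model-config files (YAML) for fitting user-supplied data from the CLI
# ---------------------------------------------------------------------------


def load_model_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "response" not in cfg:
        raise ModelSpecError(f"model config {path} must define at least 'response'")
    return cfg


def spec_from_config(cfg: dict, pedigree: Pedigree | None) -> MixedModelSpec:
    terms = []
    for item in cfg.get("random", []):
        terms.append(
            RandomTerm(
                name=item["name"],
                column=item.get("column", item["name"]),
                structure=item.get("structure", "identity"),
                role=item.get("role"),
            )
        )
    return MixedModelSpec(
        response=cfg["response"],
        fixed_factors=tuple(cfg.get("fixed", [])),
        covariates=tuple(cfg.get("covariates", [])),
        random_terms=tuple(terms),
        pedigree=pedigree,
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a delimited phenotype table (comma or tab, '#' comments)."""
    try:
        return pd.read_csv(path, sep=None, engine="python", comment="#")
    except pd.errors.ParserError as exc:
        raise ModelSpecError(f"malformed phenotype file {path}: {exc}") from exc


def fit_from_files(
    phenotype_path: str | Path,
    model_config_path: str | Path,
    pedigree_path: str | Path | None = None,
) -> tuple[ModelFit, GeneticParameters]:
    """Fit a model described by a YAML config to delimited data files."""
    cfg = load_model_config(model_config_path)
    ped = None
    ped_path = pedigree_path or cfg.get("pedigree")
    if ped_path:
        ped = read_pedigree(ped_path)
    phen = read_phenotypes(phenotype_path)
    for key, val in cfg.get("filter", {}).items():
        phen = phen[phen[key] == val]
    spec = spec_from_config(cfg, ped)
    fit = reml_fit(spec, phen)
    params = summarize_fit(
        fit,
        trait=cfg.get("trait", spec.response),
        stratum=str(cfg.get("filter", "all")),
        model=cfg.get("name", "custom"),
        include_repeatability=any(
            t.resolved_role() == "permanent_env" for t in spec.random_terms
        ),
    )
    return fit, params
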