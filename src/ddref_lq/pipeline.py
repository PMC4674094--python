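"""Model-matrix orchestration: five model variants x three data subsets.

Models: the unconstrained weighted LQ regression (``beir_vii``), the same with
positivity constraints (``hormetic``), the DerSimonian-Laird
variance-inflated refit (``heterogeneity``), the by-study-stratified
variant (``by_study``), and the individual-level Cox model (``survival``).
Subsets: all data, acute exposures only, and strata holding a direct
acute-vs-protracted comparison. The by-study and survival rows consume the
more restrictive by-study-stratified dataset.

Each model also carries the headline contrast: a likelihood-ratio test that
the strata with protracted exposures share their ratio theta with the
acute-only strata.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    AnimalRecord,
    FilterConfig,
    GroupObservation,
    StratumKey,
    apply_inclusion_filters,
    stratify_observations,
    subset_acute,
    subset_comparison,
    summarize_groups,
    write_filter_report,
)
from .heterogeneity import HeterogeneityEstimate, inflate_and_refit
from .lq_profile import (
    PROFILE_DROP,
    DdrefEstimate,
    GridSpec,
    estimate_ddref,
    lrt_theta_difference,
    profile_loglik,
)
from .survival_lq import CoxOptions, profile_cox_ddref, survival_records

logger = logging.getLogger(__name__)

__all__ = [
    "MODELS",
    "SUBSETS",
    "PipelineConfig",
    "ModelMatrixResult",
    "run_model_matrix",
    "write_report",
    "format_estimate",
]

MODELS = ("beir_vii", "hormetic", "heterogeneity", "by_study", "survival")
SUBSETS = ("all", "acute", "comparison")


@dataclass(frozen=True)
class PipelineConfig:
    grid_points: int = 401
    cox_grid_points: int = 61
    ties: str = "breslow"
    frailty: bool = True
    min_groups: int = 3
    max_total_dose: float = 1.5  # Gy
    seed: int | None = None

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_points)

    @property
    def cox_grid(self) -> GridSpec:
        return GridSpec(self.cox_grid_points)


@dataclass
class ModelMatrixResult:
    cells: dict[tuple[str, str], DdrefEstimate | None]
    reasons: dict[tuple[str, str], str]
    contrasts: dict[str, tuple[float, float]]  # model -> (LRT stat, p)
    heterogeneity: dict[str, HeterogeneityEstimate]
    cascade: list
    config: PipelineConfig
    provenance: dict = field(default_factory=dict)


def _split_by_protraction(
    strata: Mapping[StratumKey, Sequence[GroupObservation]], min_groups: int
):
    """Disjoint partition: strata holding protracted exposures vs the rest."""
    with_prot = {
        k: v for k, v in strata.items() if any(not o.group.is_acute for o in v)
    }
    without = {k: v for k, v in strata.items() if k not in with_prot}
    with_prot = {k: v for k, v in with_prot.items() if len(v) >= min_groups}
    without = {k: v for k, v in without.items() if len(v) >= min_groups}
    return with_prot, without


def _subset_strata(strata, subset: str, min_groups: int):
    if subset == "all":
        return dict(strata)
    if subset == "acute":
        return subset_acute(strata, min_groups)
    if subset == "comparison":
        return subset_comparison(strata, min_groups)
    raise ValueError(f"unknown subset {subset!r}")


def _regression_cell(
    strata, model: str, subset: str, config: PipelineConfig
) -> tuple[DdrefEstimate, HeterogeneityEstimate | None]:
    constrained = model != "beir_vii"
    if model in ("heterogeneity", "by_study"):
        est, het = inflate_and_refit(
            strata, config.grid, positive_constraints=True,
            model_label=model, subset_label=subset,
        )
        return est, het
    est = estimate_ddref(
        strata, config.grid, positive_constraints=constrained,
        model_label=model, subset_label=subset,
    )
    return est, None


def _survival_cell(animals, strata, subset: str, config: PipelineConfig):
    """Cox cell: keep only animals whose group survived the subset rules."""
    kept_groups = {o.group.group_id for v in strata.values() for o in v}
    records = [
        r for r in survival_records(animals, by_study=True)
        if r.group_id in kept_groups
    ]
    if not records:
        raise ValueError("no animals in subset")
    options = CoxOptions(
        positive_constraints=True, frailty=config.frailty, ties=config.ties
    )
    est, _, _ = profile_cox_ddref(records, config.cox_grid, options, subset)
    return est


def run_model_matrix(
    animals: Sequence[AnimalRecord],
    config: PipelineConfig | None = None,
    models: Sequence[str] = MODELS,
    subsets: Sequence[str] = SUBSETS,
) -> ModelMatrixResult:
    """Run every requested model variant on every requested data subset.

    Regression rows consume group summaries; the survival row consumes
    individual animals. Cells that cannot be estimated (e.g. no comparison
    strata survive) are marked not-estimable with a reason and the run
    continues. Deterministic given inputs and config.
    """
    config = config or PipelineConfig()
    filtered, cascade = apply_inclusion_filters(
        animals,
        FilterConfig(
            max_total_dose=config.max_total_dose,
            min_groups_per_stratum=config.min_groups,
        ),
    )
    observations = summarize_groups(filtered)
    strata_std = stratify_observations(observations, by_study=False)
    strata_std = {
        k: v for k, v in strata_std.items() if len(v) >= config.min_groups
    }
    strata_study = stratify_observations(
        observations, by_study=True, min_groups=config.min_groups
    )

    cells: dict[tuple[str, str], DdrefEstimate | None] = {}
    reasons: dict[tuple[str, str], str] = {}
    contrasts: dict[str, tuple[float, float]] = {}
    het_records: dict[str, HeterogeneityEstimate] = {}

    for model in models:
        base = strata_study if model in ("by_study", "survival") else strata_std
        for subset in subsets:
            key = (model, subset)
            try:
                strata = _subset_strata(base, subset, config.min_groups)
                if not strata:
                    raise ValueError(f"no strata survive the {subset!r} subset")
                if model == "survival":
                    cells[key] = _survival_cell(filtered, strata, subset, config)
                else:
                    est, het = _regression_cell(strata, model, subset, config)
                    cells[key] = est
                    if het is not None and subset == "all":
                        het_records[model] = het
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("cell %s not estimable: %s", key, exc)
                cells[key] = None
                reasons[key] = str(exc)

        # headline contrast on the disjoint protracted/acute-only partition
        try:
            with_prot, without = _split_by_protraction(base, config.min_groups)
            if not with_prot or not without:
                raise ValueError("degenerate partition for the contrast")
            constrained = model != "beir_vii"
            stat, p = lrt_theta_difference(
                with_prot, without, config.grid, positive_constraints=constrained
            )
            contrasts[model] = (stat, p)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("contrast for %s not estimable: %s", model, exc)
            contrasts[model] = (float("nan"), float("nan"))

    provenance = {
        "n_animals_input": len(animals),
        "n_animals_filtered": len(filtered),
        "n_groups": len(observations),
        "config": asdict(config),
        "input_checksum": _animals_checksum(animals),
    }
    return ModelMatrixResult(
        cells=cells, reasons=reasons, contrasts=contrasts,
        heterogeneity=het_records, cascade=cascade, config=config,
        provenance=provenance,
    )


def _animals_checksum(animals: Sequence[AnimalRecord]) -> str:
    h = hashlib.sha256()
    for a in animals:
        h.update(
            f"{a.animal_id},{a.group_id},{a.lifespan:.10g},{a.total_dose:.10g},"
            f"{a.fractions}\n".encode()
        )
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Reporting

def _fmt_num(x: float) -> str:
    if math.isinf(x):
        return "inf"
    return f"{x:.6g}"


def _fmt_display(x: float) -> str:
    if math.isinf(x):
        return "∞"
    return f"{x:.1f}"


def format_estimate(est: DdrefEstimate) -> str:
    """Human display: '1.3 (0.9, 3.0)' with the infinity sign at endpoints."""
    return (
        f"{_fmt_display(est.point)} "
        f"({_fmt_display(est.ci_low)}, {_fmt_display(est.ci_high)})"
    )


def write_report(result: ModelMatrixResult, out_dir) -> dict[str, Path]:
    """Write table2.tsv, contrast.json, filter_report.tsv and provenance.

    Machine columns serialize infinity as the literal token 'inf'; the display
    column uses the infinity sign. Re-running on identical inputs reproduces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows = []
    for (model, subset), est in sorted(result.cells.items()):
        if est is None:
            rows.append(
                {
                    "model": model, "subset": subset,
                    "point": "", "ci_low": "", "ci_high": "",
                    "display": f"not estimable: {result.reasons[(model, subset)]}",
                }
            )
        else:
            rows.append(
                {
                    "model": model, "subset": subset,
                    "point": _fmt_num(est.point),
                    "ci_low": _fmt_num(est.ci_low),
                    "ci_high": _fmt_num(est.ci_high),
                    "display": format_estimate(est),
                }
            )
    table_path = out / "table2.tsv"
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)
    paths["table2"] = table_path

    contrast_path = out / "contrast.json"
    contrast_payload = {
        model: {"lrt_statistic": stat, "p_value": p}
        for model, (stat, p) in sorted(result.contrasts.items())
    }
    contrast_path.write_text(json.dumps(contrast_payload, indent=2, sort_keys=True))
    paths["contrast"] = contrast_path

    report_path = out / "filter_report.tsv"
    write_filter_report(result.cascade, report_path)
    paths["filter_report"] = report_path

    het_payload = {
        model: {"tau2": h.tau2, "Q": h.q_statistic, "df": h.q_df, "p": h.p_value}
        for model, h in sorted(result.heterogeneity.items())
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(
        json.dumps(
            {"provenance": result.provenance, "heterogeneity": het_payload},
            indent=2, sort_keys=True,
        )
    )
    paths["provenance"] = prov_path
    return paths


def read_table2(path) -> pd.DataFrame:
    """Parse table2.tsv back with numeric columns ('inf' -> math.inf)."""
    df = pd.read_csv(path, sep="\t", dtype={"display": str})
    for col in ("point", "ci_low", "ci_high"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
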