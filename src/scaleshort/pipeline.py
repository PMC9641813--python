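"""End-to-end short-form development pipeline.

``ScaleReduction`` ties the stages together the way the analysis is meant
to be run: check unidimensionality (one-factor CFA), fix the number of
items with a generalizability-theory D-study, profile every item with
CTT/CFA/IRT statistics and apply the seven-criterion screen (tandem
route), and independently assemble information-optimal candidate forms of
every length and keep the shortest one meeting reliability and concurrent
validity criteria (OTA route).  The two routes are reported side by side
with an explicit agreement verdict, followed by a reliability comparison
of the chosen short form against the full form.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cfa import CFAFit, FitIndices, OneFactorCFA, fit_indices
from .ctt import cronbach_alpha, item_stats, split_half
from .data import (
    ResponseMatrix,
    ScaleDefinition,
    ValidationError,
    read_responses,
    score_distribution,
    standardized_scores,
)
from .gpcm import GPCM, GPCMResults, average_item_information
from .gt import VarianceComponents, d_study_table, g_study, min_items
from .ota import (
    AssemblyProblem,
    ShortFormEvaluation,
    assemble,
    candidate_table,
    evaluate_short_form,
    select_optimal_length,
)
from .simulate import ItemBank, load_spd10_bank, simulate_responses, simulate_thetas
from .tandem import CriteriaThresholds, ItemCriteriaProfile, criteria_table, select_items

__all__ = ["PipelineConfig", "ScaleReduction", "ScaleReductionResults", "run_pipeline"]

logger = logging.getLogger("scaleshort")


def _jsonify(obj):
    """JSON default: unwrap numpy scalars."""
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class PipelineConfig:
    """Thresholds and study settings for a full pipeline run.

    Exactly one of ``input_path`` (a response CSV) or ``simulate_n`` (draw a
    synthetic sample from ``bank_path`` or the packaged SPD-10 calibration)
    must be given.
    """

    input_path: str | None = None
    simulate_n: int | None = None
    seed: int = 0
    bank_path: str | None = None
    k_min: int = 3
    # generalizability thresholds
    gt_g_min: float = 0.70
    gt_phi_min: float = 0.70
    gt_err_max: float = 0.20
    # item-screen thresholds
    criteria: CriteriaThresholds = field(default_factory=CriteriaThresholds)
    # assembly settings
    ota_anchors: tuple[float, ...] = (-3.0, -1.0, 0.0, 1.0, 3.0)
    ota_objective: str = "sum"
    ota_alpha_ratio_min: float = 0.95
    ota_corr_min: float = 0.95
    # CFA acceptability thresholds
    cfa_cfi_min: float = 0.90
    cfa_tli_min: float = 0.90
    cfa_rmsea_max: float = 0.10
    output_dir: str | None = None

    def __post_init__(self):
        if (self.input_path is None) == (self.simulate_n is None):
            raise ValidationError(
                "exactly one of input_path or simulate_n must be provided"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        crit = raw.pop("criteria", None)
        cfg = cls(**raw)
        if crit is not None:
            if "beta_range" in crit:
                crit["beta_range"] = tuple(crit["beta_range"])
            cfg.criteria = CriteriaThresholds(**crit)
        return cfg

    def canonical_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True, default=list)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


@dataclass
class ScaleReductionResults:
    """Everything the pipeline computed, with a printable summary."""

    config: PipelineConfig
    # unidimensionality
    cfa_fit: CFAFit
    cfa_indices: FitIndices
    unidimensional: bool
    # generalizability
    variance_components: VarianceComponents
    d_table: pd.DataFrame
    k_gt: int | None
    # item calibration
    gpcm: GPCMResults
    full_alpha: float
    criteria: pd.DataFrame
    profiles: list[ItemCriteriaProfile]
    # the two routes
    tandem_items: ScaleDefinition | None
    tandem_eval: ShortFormEvaluation | None
    ota_eval: ShortFormEvaluation
    ota_candidates: list[ShortFormEvaluation]
    routes_agree: bool
    # final short form
    short_form: ScaleDefinition
    reliability: pd.DataFrame
    seed: int

    @property
    def short_form_eval(self) -> ShortFormEvaluation:
        if self.tandem_eval is not None and tuple(self.short_form.item_ids) == self.tandem_eval.items:
            return self.tandem_eval
        return self.ota_eval

    def provenance(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config.digest(),
            "version": __version__,
        }

    def to_dict(self) -> dict:
        ev = self.short_form_eval
        return {
            "provenance": self.provenance(),
            "unidimensionality": {
                "cfi": self.cfa_indices.cfi,
                "tli": self.cfa_indices.tli,
                "rmsea": self.cfa_indices.rmsea,
                "acceptable": self.unidimensional,
            },
            "variance_components": asdict(self.variance_components),
            "d_study": self.d_table.to_dict(orient="records"),
            "k_gt": self.k_gt,
            "full_alpha": self.full_alpha,
            "criteria": json.loads(self.criteria.to_json(orient="records")),
            "tandem_items": list(self.tandem_items.item_ids) if self.tandem_items else None,
            "ota_items": list(self.ota_eval.items),
            "ota_candidates": [
                {
                    "k": e.k,
                    "items": list(e.items),
                    "cronbach_alpha": e.cronbach_alpha,
                    "corr_factor": e.corr_factor,
                    "corr_total": e.corr_total,
                    "passes": e.passes,
                }
                for e in self.ota_candidates
            ],
            "routes_agree": self.routes_agree,
            "short_form": {
                "items": list(self.short_form.item_ids),
                "cronbach_alpha": ev.cronbach_alpha,
                "corr_total": ev.corr_total,
                "corr_factor": ev.corr_factor,
            },
            "reliability": self.reliability.to_dict(orient="records"),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_jsonify)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        idx = self.cfa_indices
        lines = [
            "Scale reduction summary",
            "=" * 64,
            f"Full form: {len(self.criteria)} items, Cronbach alpha = {self.full_alpha:.3f}",
            f"Unidimensionality (one-factor CFA): CFI={idx.cfi:.3f} "
            f"TLI={idx.tli:.3f} RMSEA={idx.rmsea:.3f} -> "
            + ("acceptable" if self.unidimensional else "NOT acceptable"),
            "",
            "D-study (generalizability projection):",
        ]
        for _, row in self.d_table.iterrows():
            lines.append(
                f"  n'={int(row.n_items):>2}  G={row.G:.3f}  phi={row.phi:.3f}  "
                f"rel_err={row.rel_err:.3f}  abs_err={row.abs_err:.3f}"
            )
        lines.append(
            f"Required items (GT): {self.k_gt if self.k_gt is not None else 'none met thresholds'}"
        )
        lines += ["", "Item screen (criteria satisfied):"]
        for _, row in self.criteria.iterrows():
            lines.append(f"  {row.item_id:<8} {int(row.n_criteria)}/7")
        tand = " ".join(self.tandem_items.item_ids) if self.tandem_items else "-"
        lines += [
            "",
            f"Tandem route (GT+CTT+IRT): {tand}",
            f"OTA route (k={self.ota_eval.k}): {' '.join(self.ota_eval.items)}"
            + ("" if self.ota_eval.passes else "  [no candidate met the criteria]"),
            f"Routes agree: {'yes' if self.routes_agree else 'no'}",
            "",
            f"Short form ({len(self.short_form)} items): {' '.join(self.short_form.item_ids)}",
        ]
        ev = self.short_form_eval
        lines.append(
            f"  alpha={ev.cronbach_alpha:.3f} (full {ev.full_alpha:.3f}), "
            f"corr(total)={ev.corr_total:.3f}, corr(factor)={ev.corr_factor:.3f}"
        )
        lines += ["", "Reliability comparison:"]
        for _, row in self.reliability.iterrows():
            lines.append(
                f"  {row['scale']:<6} k={int(row['n_items']):>2}  "
                f"alpha={row['cronbach_alpha']:.3f}  split-half={row['split_half']:.3f}  "
                f"score {row['score_min']:.2f}~{row['score_max']:.2f}  "
                f"median {row['median']:.2f} ({row['q1']:.2f}~{row['q3']:.2f})  "
                f"mean {row['mean']:.2f}"
            )
        return "\n".join(lines)


class ScaleReduction:
    """Short-form development model for one response matrix.

    Parameters
    ----------
    data : ResponseMatrix
        The full-form responses.
    config : PipelineConfig, optional
        Thresholds and settings; a default configuration is built around the
        data when omitted.
    """

    def __init__(self, data: ResponseMatrix, config: PipelineConfig | None = None):
        self.data = data
        if config is None:
            config = PipelineConfig(input_path="<in-memory>")
        self.config = config

    def fit(self) -> ScaleReductionResults:
        cfg = self.config
        m = self.data
        full = m.full_scale()
        k_range = range(cfg.k_min, m.n_items + 1)

        logger.info("stage 1/6: one-factor CFA (unidimensionality)")
        try:
            cfa_fit = OneFactorCFA(m).fit()
        except ValidationError as err:
            raise ValidationError(f"CFA stage failed: {err}") from err
        idx = fit_indices(cfa_fit)
        unidim = (
            idx.cfi >= cfg.cfa_cfi_min
            and idx.tli >= cfg.cfa_tli_min
            and idx.rmsea <= cfg.cfa_rmsea_max
        )
        if not unidim:
            logger.warning("one-factor fit below thresholds; proceeding with verdict recorded")

        logger.info("stage 2/6: G-study / D-study")
        vc = g_study(m)
        d_tab = d_study_table(vc, k_range)
        k_gt = min_items(vc, k_range, cfg.gt_g_min, cfg.gt_phi_min, cfg.gt_err_max)

        logger.info("stage 3/6: GPCM marginal-ML fit")
        gpcm_res = GPCM(m).fit()

        logger.info("stage 4/6: CTT statistics and item screen")
        full_alpha = cronbach_alpha(m)
        stats = item_stats(m)
        loadings = dict(zip(cfa_fit.item_ids, cfa_fit.loadings))
        profiles = [
            ItemCriteriaProfile(
                item_id=s.item_id,
                item_total_r=s.item_total_r,
                alpha_if_deleted=s.alpha_if_deleted,
                citc=s.citc,
                loading=float(loadings[s.item_id]),
                alpha_irt=gpcm_res.bank[s.item_id].alpha,
                betas=gpcm_res.bank[s.item_id].betas,
                avg_info=average_item_information(gpcm_res.bank[s.item_id]),
            )
            for s in stats
        ]
        crit_tab = criteria_table(profiles, full_alpha, cfg.criteria)

        logger.info("stage 5/6: tandem selection and OTA")
        if k_gt is not None:
            tandem_items = select_items(profiles, k_gt, full_alpha, cfg.criteria)
            tandem_eval = evaluate_short_form(
                m, tandem_items, full, gpcm_res.bank,
                cfg.ota_alpha_ratio_min, cfg.ota_corr_min,
            )
        else:
            logger.warning("no form length met the GT thresholds; tandem route skipped")
            tandem_items, tandem_eval = None, None
        ota_eval, ota_cands = select_optimal_length(
            m, gpcm_res.bank, k_range, cfg.ota_anchors, cfg.ota_objective,
            cfg.ota_alpha_ratio_min, cfg.ota_corr_min,
        )
        routes_agree = (
            tandem_items is not None
            and tuple(tandem_items.item_ids) == tuple(ota_eval.items)
        )
        short = tandem_items if tandem_items is not None else ScaleDefinition(
            ota_eval.items, m.n_categories, m.min_category
        )

        logger.info("stage 6/6: reliability comparison")
        reliability = self._reliability_table(m, full, short)

        return ScaleReductionResults(
            config=cfg,
            cfa_fit=cfa_fit,
            cfa_indices=idx,
            unidimensional=unidim,
            variance_components=vc,
            d_table=d_tab,
            k_gt=k_gt,
            gpcm=gpcm_res,
            full_alpha=full_alpha,
            criteria=crit_tab,
            profiles=profiles,
            tandem_items=tandem_items,
            tandem_eval=tandem_eval,
            ota_eval=ota_eval,
            ota_candidates=ota_cands,
            routes_agree=routes_agree,
            short_form=short,
            reliability=reliability,
            seed=cfg.seed,
        )

    @staticmethod
    def _reliability_table(m, full, short) -> pd.DataFrame:
        rows = []
        for label, scale in (("full", full), ("short", short)):
            scores = standardized_scores(m, scale)
            summ = score_distribution(scores)
            rows.append(
                {
                    "scale": label,
                    "n_items": len(scale),
                    "cronbach_alpha": cronbach_alpha(m, scale),
                    "split_half": split_half(m, scale),
                    "score_min": summ.minimum,
                    "score_max": summ.maximum,
                    "median": summ.median,
                    "q1": summ.q1,
                    "q3": summ.q3,
                    "mean": summ.mean,
                }
            )
        return pd.DataFrame(rows)


def _load_input(cfg: PipelineConfig) -> tuple[ResponseMatrix, ItemBank | None]:
    if cfg.input_path is not None:
        return read_responses(cfg.input_path), None
    bank = ItemBank.from_json(cfg.bank_path) if cfg.bank_path else load_spd10_bank()
    thetas = simulate_thetas(cfg.simulate_n, cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    return simulate_responses(bank, thetas, rng), bank


def run_pipeline(cfg: PipelineConfig) -> ScaleReductionResults:
    """Load or simulate the data per the config, fit, and write reports.

    When ``cfg.output_dir`` is set, the intermediate tables (D-study,
    criteria, OTA candidates, reliability comparison) are written as CSV and
    the full report as JSON.
    """
    m, _ = _load_input(cfg)
    results = ScaleReduction(m, cfg).fit()
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.d_table.to_csv(out / "d_study.csv", index=False)
        results.criteria.to_csv(out / "criteria.csv", index=False)
        candidate_table(results.ota_candidates).to_csv(out / "ota_candidates.csv", index=False)
        results.reliability.to_csv(out / "reliability.csv", index=False)
        results.to_json(out / "report.json")
        logger.info("reports written to %s", out)
    return results
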