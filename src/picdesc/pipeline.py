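"""End-to-end orchestration: extract features, build consensus, estimate
reliability, screen associations, compute group odds ratios, and factor the
screened variables — per rated characteristic — with deterministic outputs.

Every stage writes plain CSV/JSON so intermediates can be inspected or
replaced; the machine-readable ``summary.json`` is byte-identical across
runs with the same inputs and seed (timestamps go to the log, never the
summary). Stage failures raise :class:`PipelineStageError` naming the stage.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, efa as efa_mod, ratings as ratings_mod
from .corpus_io import (
    EmbeddingTable,
    NormsTable,
    read_embeddings,
    read_labels_csv,
    read_norms_table,
    read_ratings_csv,
    read_transcript_json,
)
from .linguistic import ContentLexicon, extract_all, feature_manifest, load_content_lexicon, write_feature_manifest
from .simulate import (
    CHARACTERISTICS,
    SyntheticCohortConfig,
    simulate_cohort,
    simulate_rating_panel,
    simulate_waveform,
)

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline", "extract_feature_matrix"]

GROUP_PAIRS = (("AD", "HC"), ("MCI", "HC"), ("AD", "MCI"))


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run.

    Either ``simulate`` is True (synthetic cohort, the default) or
    ``corpus_dir``/``ratings_csv``/``labels_csv`` point at transcript JSON
    files plus rating and label tables.
    """

    out_dir: str | Path = "results/run"
    seed: int = 0
    simulate: bool = True
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    include_audio: bool = True
    picture_features: bool = True
    characteristics: tuple[str, ...] = CHARACTERISTICS
    alpha: float = 0.05
    cutoff: float = 0.6
    pa_iterations: int = 100
    pa_percentile: float = 95.0
    impaired_threshold: int = 1
    # corpus-mode inputs
    corpus_dir: str | Path | None = None
    ratings_csv: str | Path | None = None
    labels_csv: str | Path | None = None
    norms_tsv: str | Path | None = None
    embeddings_txt: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.characteristics:
            raise ValueError("characteristics must be non-empty")


def _setup_logger(out_dir: Path) -> logging.Logger:
    logger = logging.getLogger(f"picdesc.pipeline.{out_dir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s [%(levelname)s] %(message)s")
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(fmt)
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(fh)
    logger.addHandler(sh)
    logger.propagate = False
    return logger


def extract_feature_matrix(
    transcripts,
    audio_map=None,
    norms: NormsTable | None = None,
    embeddings: EmbeddingTable | None = None,
    lexicon: ContentLexicon | None = None,
) -> pd.DataFrame:
    """Run the full extractor over a corpus; rows are samples, columns the
    canonical feature names, missing values NaN."""
    rows = {}
    for t in transcripts:
        audio = audio_map.get(t.sample_id) if audio_map else None
        feats = extract_all(t, audio=audio, norms=norms, embeddings=embeddings, lexicon=lexicon)
        rows[t.sample_id] = {k: (np.nan if v is None else v) for k, v in feats.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also written to
    ``<out_dir>/summary.json``)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger = _setup_logger(out_dir)
    summary: dict = {"seed": config.seed, "characteristics": {}}

    # ---- inputs ----------------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate:
            logger.info("simulating cohort (seed=%d)", config.seed)
            cohort = simulate_cohort(config.cohort, seed=config.seed)
            transcripts = cohort.transcripts
            labels = cohort.labels
            norms, embeddings, lexicon = cohort.norms, cohort.embeddings, cohort.lexicon
            panel = simulate_rating_panel(
                cohort.true_severities.reindex(columns=list(config.characteristics)),
                n_raters=config.cohort.n_raters,
                rater_sd=config.cohort.rater_sd,
                seed=config.seed,
            )
            audio_map = None
            if config.include_audio:
                audio_map = {
                    t.sample_id: simulate_waveform(t, seed=config.seed + i,
                                                   rate=config.cohort.sample_rate)
                    for i, t in enumerate(transcripts)
                }
        else:
            if config.corpus_dir is None or config.ratings_csv is None or config.labels_csv is None:
                raise ValueError("corpus mode needs corpus_dir, ratings_csv and labels_csv")
            transcripts = tuple(
                read_transcript_json(p) for p in sorted(Path(config.corpus_dir).glob("*.json"))
            )
            labels = read_labels_csv(config.labels_csv)
            panel = read_ratings_csv(config.ratings_csv)
            norms = read_norms_table(config.norms_tsv) if config.norms_tsv else None
            embeddings = read_embeddings(config.embeddings_txt) if config.embeddings_txt else None
            lexicon = load_content_lexicon()
            audio_map = None
        summary["n_samples"] = len(transcripts)
        summary["groups"] = {g: int((labels == g).sum()) for g in sorted(set(labels))}
    except PipelineStageError:
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- extraction ------------------------------------------------------
    stage = "extract"
    try:
        if config.picture_features and embeddings is None:
            raise PipelineStageError(
                "picture_similarity",
                "picture features requested but no embedding table available",
            )
        logger.info("extracting features for %d samples", len(transcripts))
        features = extract_feature_matrix(
            transcripts, audio_map=audio_map, norms=norms,
            embeddings=embeddings if config.picture_features else None, lexicon=lexicon,
        )
        features.to_csv(out_dir / "features.csv")
        write_feature_manifest(out_dir / "feature_manifest.tsv")
        summary["n_features"] = int(features.shape[1])
    except PipelineStageError as exc:
        logger.error(str(exc))
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineStageError(stage, str(exc)) from exc

    family = {name: fam for name, fam, _ in feature_manifest()}
    rho_sign_check: dict[str, float] = {}

    consensus_rows = []
    icc_rows = []
    for ci, characteristic in enumerate(config.characteristics):
        char_summary: dict = {}
        # ---- consensus + reliability ------------------------------------
        stage = f"consensus[{characteristic}]"
        try:
            sub = panel.characteristic(characteristic)
            cons = ratings_mod.consensus_rating(sub)
            icc_res = ratings_mod.icc(sub)
            for sample_id, value in cons.consensus.items():
                consensus_rows.append({
                    "sample_id": sample_id, "characteristic": characteristic,
                    "consensus": int(value), "flagged": bool(cons.flagged[sample_id]),
                })
            icc_rows.append({
                "characteristic": characteristic,
                "icc_single": icc_res.icc_single, "icc_average": icc_res.icc_average,
                "f_stat": icc_res.f_stat, "p_value": icc_res.p_value, "band": icc_res.band,
            })
            char_summary["icc_single"] = icc_res.icc_single
            char_summary["icc_average"] = icc_res.icc_average
            char_summary["icc_band"] = icc_res.band
            char_summary["n_flagged"] = int(cons.flagged.sum())
            logger.info("%s: ICC(2,1)=%.3f (%s)", characteristic,
                        icc_res.icc_single, icc_res.band)
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            raise PipelineStageError(stage, str(exc)) from exc

        # ---- screen ------------------------------------------------------
        stage = f"screen[{characteristic}]"
        try:
            screen = association.spearman_screen(
                features, cons.consensus, alpha=config.alpha,
            )
            screen_df = pd.DataFrame([
                {"feature": r.feature, "rho": r.rho, "p": r.p_value,
                 "n": r.n_used, "selected": r.selected}
                for r in screen
            ])
            screen_df.to_csv(out_dir / f"screen_{characteristic}.csv", index=False)
            selected = [r for r in screen if r.selected]
            char_summary["n_selected"] = len(selected)
            for r in screen:
                rho_sign_check[f"{characteristic}:{r.feature}"] = r.rho
            logger.info("%s: %d/%d features selected at p<%.2f", characteristic,
                        len(selected), len(screen), config.alpha)
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            raise PipelineStageError(stage, str(exc)) from exc

        # ---- odds ratios -------------------------------------------------
        stage = f"odds[{characteristic}]"
        try:
            or_rows = []
            char_summary["odds_ratios"] = {}
            for a, b in GROUP_PAIRS:
                res = association.group_odds_ratio(
                    cons.consensus, labels, a, b,
                    impaired_threshold=config.impaired_threshold,
                )
                (ta, tb), (tc, td) = res.table
                or_rows.append({
                    "characteristic": characteristic, "groupA": a, "groupB": b,
                    "a": ta, "b": tb, "c": tc, "d": td,
                    "or": res.or_estimate, "lo": res.ci95[0], "hi": res.ci95[1],
                    "corrected": res.corrected,
                })
                char_summary["odds_ratios"][f"{a}_vs_{b}"] = res.or_estimate
            pd.DataFrame(or_rows).to_csv(out_dir / f"odds_{characteristic}.csv", index=False)
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            raise PipelineStageError(stage, str(exc)) from exc

        # ---- EFA ---------------------------------------------------------
        stage = f"efa[{characteristic}]"
        try:
            if selected:
                cols = [r.feature for r in selected]
                sub_features = features[cols]
                # mean-impute the few missing cells so PA/PAF see a full matrix
                sub_features = sub_features.fillna(sub_features.mean())
                efa_res = efa_mod.run_efa(
                    sub_features, cutoff=config.cutoff,
                    n_iter_pa=config.pa_iterations, percentile=config.pa_percentile,
                    seed=config.seed * 1000 + ci,
                )
                rho_map = {r.feature: r.rho for r in selected}
                report_rows = []
                for i, var in enumerate(efa_res.variables):
                    row = {"variable": var, "family": family.get(var, ""),
                           "rho": rho_map[var]}
                    for j in range(efa_res.k):
                        loading = efa_res.pattern[i, j]
                        row[f"F{j + 1}"] = (
                            loading if (abs(loading) >= config.cutoff
                                        and efa_res.assignments[var] == j) else ""
                        )
                    report_rows.append(row)
                pd.DataFrame(report_rows).to_csv(
                    out_dir / f"efa_{characteristic}.csv", index=False)
                char_summary["k_factors"] = efa_res.k
                char_summary["var_prop_pct"] = [round(100 * v, 1) for v in efa_res.var_prop]
                char_summary["n_assigned"] = sum(
                    1 for v in efa_res.assignments.values() if v is not None)
                logger.info("%s: EFA retained k=%d factor(s)", characteristic, efa_res.k)
            else:
                char_summary["k_factors"] = 0
                char_summary["var_prop_pct"] = []
                char_summary["n_assigned"] = 0
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            raise PipelineStageError(stage, str(exc)) from exc

        summary["characteristics"][characteristic] = char_summary

    pd.DataFrame(consensus_rows).to_csv(out_dir / "consensus.csv", index=False)
    pd.DataFrame(icc_rows).to_csv(out_dir / "icc.csv", index=False)

    summary_text = json.dumps(_round_floats(summary), indent=1, sort_keys=True)
    (out_dir / "summary.json").write_text(summary_text + "\n", encoding="utf-8")
    logger.info("run complete: %s", out_dir / "summary.json")
    for h in logger.handlers:
        h.close()
    logger.handlers.clear()
    return summary
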