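"""End-to-end orchestration: SVM prediction, conservation mining, and the
union combiner.

The two predictors are complementary — the SVM is precise but conservative,
while conserved-residue mining recovers binding residues the SVM misses —
so their calls are combined by elementwise OR.  When the miner cannot
produce patterns (too few usable homologs), the combined result falls back
to the SVM calls alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from proterna.conservation_miner import (
    HomologSet,
    MinerConfig,
    NoPatternError,
    mine_patterns,
    pattern_calls,
    write_patterns_tsv,
)
from proterna.evaluation import MetricReport, confusion, metrics
from proterna.features import EncodingConfig, encode_chain
from proterna.profiles import ProfileSet
from proterna.svm_predictor import (
    PredictionResult,
    TrainedModel,
    predict,
    write_predictions_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class CombinedPrediction:
    """Union of SVM and conservation calls with per-position provenance."""

    chain_id: str
    svm_calls: np.ndarray
    conservation_calls: np.ndarray | None
    combined_calls: np.ndarray
    provenance: list[str]  # per position: svm | conservation | both | none


def combine_union(
    svm: PredictionResult, cons: Sequence[int] | None
) -> CombinedPrediction:
    """OR-combine SVM calls with conservation calls.

    An absent conservation vector (miner produced no patterns) leaves the
    SVM calls unchanged.
    """
    svm_calls = np.asarray(svm.calls, dtype=int)
    if cons is None:
        return CombinedPrediction(
            chain_id=svm.chain_id,
            svm_calls=svm_calls,
            conservation_calls=None,
            combined_calls=svm_calls.copy(),
            provenance=["svm" if c else "none" for c in svm_calls],
        )
    cons_calls = np.asarray(cons, dtype=int)
    if cons_calls.shape != svm_calls.shape:
        raise ValueError("SVM and conservation call vectors differ in length")
    combined = (svm_calls | cons_calls).astype(int)
    provenance = []
    for s, c in zip(svm_calls, cons_calls):
        if s and c:
            provenance.append("both")
        elif s:
            provenance.append("svm")
        elif c:
            provenance.append("conservation")
        else:
            provenance.append("none")
    return CombinedPrediction(
        chain_id=svm.chain_id,
        svm_calls=svm_calls,
        conservation_calls=cons_calls,
        combined_calls=combined,
        provenance=provenance,
    )


@dataclass
class PipelineResult:
    combined: CombinedPrediction
    svm_result: PredictionResult
    patterns: list | None
    report: MetricReport | None
    notices: list[str] = field(default_factory=list)


def run_pipeline(
    profiles: ProfileSet,
    model: TrainedModel,
    homologs: HomologSet | None = None,
    labels: Sequence[int] | None = None,
    miner_config: MinerConfig = MinerConfig(),
    encoding: EncodingConfig = EncodingConfig(),
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Featurize → SVM predict → mine → combine → (optionally) evaluate.

    Stage failures are reported with their stage name; a miner that finds no
    patterns downgrades to SVM-only prediction with a logged notice.  With
    ``out_dir`` set, each stage's artifact is written as TSV.
    """
    notices: list[str] = []
    try:
        feats = encode_chain(profiles, encoding)
    except Exception as exc:
        raise RuntimeError(f"featurize stage failed: {exc}") from exc
    try:
        svm_result = predict(model, feats)
    except Exception as exc:
        raise RuntimeError(f"svm stage failed: {exc}") from exc

    patterns = None
    cons_calls = None
    if homologs is not None:
        try:
            patterns = mine_patterns(homologs, miner_config)
            cons_calls = pattern_calls(patterns, profiles.n_residues)
        except NoPatternError as exc:
            notices.append(f"miner produced no patterns: {exc}; using SVM only")
            logger.info(notices[-1])
    else:
        notices.append("no homologs supplied; using SVM only")

    combined = combine_union(svm_result, cons_calls)

    report = None
    if labels is not None:
        try:
            report = metrics(confusion(labels, combined.combined_calls))
        except Exception as exc:
            raise RuntimeError(f"evaluate stage failed: {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "svm_predictions.tsv").write_text(write_predictions_tsv(svm_result))
        if patterns is not None:
            (out / "patterns.tsv").write_text(write_patterns_tsv(patterns))
        (out / "combined.tsv").write_text(combined_to_tsv(combined))
        if report is not None:
            (out / "metrics.txt").write_text(report.summary() + "\n")
        if notices:
            (out / "notices.log").write_text("\n".join(notices) + "\n")

    return PipelineResult(
        combined=combined,
        svm_result=svm_result,
        patterns=patterns,
        report=report,
        notices=notices,
    )


def combined_to_tsv(combined: CombinedPrediction) -> str:
    lines = ["chain_id\tresidue_index\tsvm\tconservation\tcombined\tprovenance"]
    cons = combined.conservation_calls
    for i in range(len(combined.combined_calls)):
        c = "." if cons is None else str(cons[i])
        lines.append(
            f"{combined.chain_id}\t{i + 1}\t{combined.svm_calls[i]}\t{c}\t"
            f"{combined.combined_calls[i]}\t{combined.provenance[i]}"
        )
    return "\n".join(lines) + "\n"
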