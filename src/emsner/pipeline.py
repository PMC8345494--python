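"""End-to-end orchestration: generate (or load) reports, pseudo-label,
split, train, predict, evaluate.

Each stage is individually callable through the library (or the CLI); this
module is exactly their composition, with one global seed propagated to
every stochastic stage and every intermediate artifact persisted when an
output directory is given.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .dataset import Corpus, split_corpus, write_conll
from .evaluation import EvaluationReport, evaluate_corpus
from .lexicon import Lexicon, load_lexicon, starter_lexicon
from .synthetic import GeneratorConfig, generate_corpus
from .tagger import BiLstmCrfTagger, TaggerConfig, train
from .tags import mentions_to_iob2
from .weak_labeler import MatcherConfig, weak_label

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One seed, one lexicon, and the per-stage configurations."""

    seed: int = 0
    lexicon_path: str | None = None  # None -> packaged starter lexicon
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    matcher: MatcherConfig = field(default_factory=MatcherConfig)
    tagger: TaggerConfig = field(default_factory=TaggerConfig)
    fractions: tuple[float, float, float] = (0.90, 0.05, 0.05)
    out_dir: str | None = None


@dataclass
class PipelineResult:
    model: BiLstmCrfTagger
    history: list[dict]
    report: EvaluationReport
    gold_test: Corpus
    pred_test: Corpus


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Synthesize -> weak-label -> split -> train -> predict -> evaluate.

    The training and development splits carry gazetteer pseudo-labels (the
    weak-supervision regime); the held-out test split keeps its clean gold
    labels, so the final scores measure recovery of true spans, not
    agreement with the labeler.
    """
    if config.lexicon_path:
        lexicon = load_lexicon(config.lexicon_path)
    else:
        lexicon = starter_lexicon()

    gen_cfg = dataclasses.replace(config.generator, seed=config.seed)
    tag_cfg = dataclasses.replace(config.tagger, seed=config.seed)

    logger.info("generating %d synthetic reports", gen_cfg.n_reports)
    gold_corpus, _ = generate_corpus(gen_cfg, lexicon)

    gold_train, gold_dev, gold_test = split_corpus(
        gold_corpus, config.fractions, seed=config.seed
    )

    def pseudo_label(corpus: Corpus, tag: str) -> Corpus:
        out = []
        for rep, _ in corpus:
            tags, _ = weak_label(rep, lexicon, config.matcher)
            out.append((rep, tags))
        return Corpus(out, tag)

    weak_train = pseudo_label(gold_train, "train")
    weak_dev = pseudo_label(gold_dev, "dev")

    logger.info("training BiLSTM-CRF on %d weak-labeled reports", len(weak_train))
    model, history = train(weak_train, weak_dev, tag_cfg)

    pred_rows = []
    for rep, _ in gold_test:
        mentions = model.predict(rep)
        pred_rows.append((rep, mentions_to_iob2(mentions, len(rep.tokens))))
    pred_test = Corpus(pred_rows, "test")

    report = evaluate_corpus(gold_test, pred_test)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_conll(weak_train, out / "train.conll")
        write_conll(weak_dev, out / "dev.conll")
        write_conll(gold_test, out / "test_gold.conll")
        write_conll(pred_test, out / "test_pred.conll")
        model.save(out / "model.npz")
        report.to_table().to_csv(out / "results.tsv", sep="\t", index=False)
        with open(out / "history.json", "w", encoding="utf-8") as fh:
            json.dump(history, fh, indent=2)
    return PipelineResult(model, history, report, gold_test, pred_test)
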