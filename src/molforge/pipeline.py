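"""Config-driven orchestration of the design funnel.

Stages: synthesize a training corpus -> pretrain the SMILES language model ->
fine-tune on a focused analog series -> sample -> generation-quality report
-> lead-like funnel (properties, alerts, novelty, RAFSF feasibility,
toxicity plug-ins) -> machine-readable summary with the count surviving each
stage. Every stage writes its output under the run directory and is skipped
on re-run if the output already exists (resume); config and seeds fully
determine every artifact, so two clean runs with the same config produce
byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import chem, filters, fixtures, generator, rafsf
from .generator import GeneratorConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run; serialized into the summary header."""

    out_dir: str = "molforge_run"
    seed: int = 0
    # corpus stage
    corpus_size: int = 300
    # model stages
    pretrain_epochs: int = 8
    finetune_epochs: int = 4
    n_focused: int = 20
    n_samples: int = 300
    temperature: float = 1.0
    model: GeneratorConfig = field(default_factory=GeneratorConfig)
    # funnel stage
    rafsf_threshold: float = 6.0
    mw_window: tuple[float, float] = (200.0, 600.0)
    logp_window: tuple[float, float] = (-1.0, 6.0)
    resume: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        model = GeneratorConfig(**raw.pop("model", {}))
        cfg = cls(**raw)
        cfg.model = model
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mw_window"] = list(d["mw_window"])
        d["logp_window"] = list(d["logp_window"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(path: Path, resume: bool) -> bool:
    """True if the stage must run (output missing or resume disabled)."""
    return not (resume and path.exists())


def run_pipeline(config: RunConfig) -> dict:
    """Execute the funnel end to end; returns the summary dict.

    Any stage failure propagates after partial outputs have been persisted,
    so a fixed run can be resumed once the cause is addressed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = fixtures.FixtureSpec(corpus_size=config.corpus_size, seed=config.seed)

    corpus_path = out / "corpus.smi"
    if _stage(corpus_path, config.resume):
        logger.info("stage corpus: generating %d molecules", config.corpus_size)
        corpus = fixtures.generate_corpus(spec)
        corpus_path.write_text("\n".join(corpus) + "\n")
    corpus = [l for l in corpus_path.read_text().splitlines() if l.strip()]

    model_path = out / "pretrained.npz"
    if _stage(model_path, config.resume):
        logger.info("stage pretrain: %d epochs", config.pretrain_epochs)
        model = generator.pretrain(
            corpus, config.pretrain_epochs, seed=config.seed, config=config.model
        )
        model.save(model_path)
    model = generator.SmilesGenerator.load(model_path)

    # focused set: nearest corpus analogs of the designated query compound
    query = fixtures.query_compound(spec)
    focused = _nearest_analogs(query, corpus, config.n_focused)
    focused_path = out / "focused.smi"
    focused_path.write_text("\n".join(focused) + "\n")

    tuned_path = out / "finetuned.npz"
    if _stage(tuned_path, config.resume):
        logger.info("stage finetune: %d epochs on %d analogs", config.finetune_epochs, len(focused))
        tuned = generator.fine_tune(model, focused, config.finetune_epochs, seed=config.seed)
        tuned.save(tuned_path)
    tuned = generator.SmilesGenerator.load(tuned_path)

    samples_path = out / "samples.smi"
    if _stage(samples_path, config.resume):
        logger.info("stage sample: n=%d", config.n_samples)
        samples = tuned.sample(config.n_samples, config.temperature, seed=config.seed)
        samples_path.write_text("\n".join(samples) + "\n")
    samples = samples_path.read_text().splitlines()

    report = generator.evaluate_generation(samples, corpus, reference_actives=focused, seed=config.seed)
    (out / "generation_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )

    space = rafsf.build_fragment_space(corpus, corpus_id="run-corpus")
    space.save(out / "fragment_space.tsv")
    valid_unique = sorted(
        {chem.canonicalize(s) for s in samples if chem.is_valid_smiles(s)}
    )
    funnel_cfg = filters.FunnelConfig(
        windows={"mw": config.mw_window, "logp": config.logp_window},
        reference_actives=tuple(corpus),
        fragment_space=space,
        rafsf_threshold=config.rafsf_threshold,
    )
    records = [
        chem.MoleculeRecord.from_smiles(s, f"hit{i:05d}") for i, s in enumerate(valid_unique)
    ]
    verdicts, survivors = filters.apply_funnel(records, funnel_cfg)
    filters.write_verdicts_csv(verdicts, out / "verdicts.csv")
    (out / "survivors.smi").write_text(
        "\n".join(f"{r.smiles_canonical}\t{r.id}" for r in survivors) + "\n"
    )

    summary = {
        "config": config.to_dict(),
        "funnel": {
            "sampled": len(samples),
            "valid_unique": len(valid_unique),
            "survivors": len(survivors),
        },
        "generation_report": report.to_dict(),
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "summary.json"
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _nearest_analogs(query: str, corpus: list[str], k: int) -> list[str]:
    from .chem import FingerprintKind, SimilarityMeasure

    qfp = chem.fingerprint(query, FingerprintKind.CIRCULAR)
    scored = sorted(
        corpus,
        key=lambda s: (
            -chem.similarity(
                qfp, chem.fingerprint(s, FingerprintKind.CIRCULAR), SimilarityMeasure.TANIMOTO
            ),
            s,
        ),
    )
    return scored[:k]
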