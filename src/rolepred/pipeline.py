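"""Configuration-driven end-to-end orchestration.

One YAML config drives: corpus generation per language preset, next-word
pretraining, k-fold cross-validated role training, predictability record
extraction, hierarchical beta regression with language contrasts, and a
JSON report.  Every emitted file is content-hashed into ``manifest.json``;
a rerun with an identical config reproduces an identical records table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .bayes import RegressionSpec, build_design, fit_beta_hierarchical, pairwise_language_contrasts
from .bayes.glmm import ConvergenceError
from .corpus import corpus_statistics, write_corpus
from .model import ModelConfig, kfold_evaluate, make_vocab, pretrain
from .predictability import extract_records, records_to_frame, write_records
from .synth import LanguageSpec, generate_adu_text, generate_cdu_corpus, preset_path

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]

log = logging.getLogger("rolepred.pipeline")


@dataclass
class PipelineConfig:
    presets: list[str]                  # preset names or YAML paths
    out_dir: str
    n_cdu: int = 500
    n_adu_words: int = 4000
    k_folds: int = 5
    seed: int = 0
    skip_pretrain: bool = False
    skip_regression: bool = False
    model: dict = field(default_factory=dict)
    regression: dict = field(default_factory=dict)

    def resolve_presets(self) -> list[Path]:
        paths = []
        for p in self.presets:
            cand = Path(p)
            if not cand.exists():
                try:
                    cand = preset_path(p)
                except KeyError:
                    raise FileNotFoundError(f"preset not found: {p!r}")
            if not cand.exists():
                raise FileNotFoundError(f"preset file missing: {cand}")
            paths.append(cand)
        return paths

    def validate(self) -> None:
        self.resolve_presets()
        if self.n_cdu < self.k_folds:
            raise ValueError("n_cdu must be >= k_folds")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, root: Path):
        self.root = root
        self.entries: dict[str, str] = {}

    def register(self, path: Path) -> None:
        self.entries[str(path.relative_to(self.root))] = _sha256(path)

    def write(self) -> None:
        out = self.root / "manifest.json"
        out.write_text(json.dumps(self.entries, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the artifact directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    mconfig = ModelConfig(**{**config.model, "seed": config.seed})

    all_records = []
    report: dict = {"languages": {}, "seed": config.seed}
    for preset_file in config.resolve_presets():
        spec = LanguageSpec.from_yaml(preset_file)
        t0 = time.time()
        log.info("generating corpus for %s", spec.name)
        try:
            corpus, gen_log = generate_cdu_corpus(spec, config.n_cdu, config.seed, return_log=True)
            cpath = out / f"{spec.name}.cdu.jsonl"
            write_corpus(corpus, cpath)
            manifest.register(cpath)
            lpath = out / f"{spec.name}.cdu.log.jsonl"
            lpath.write_text(
                "\n".join(json.dumps(e, sort_keys=True) for e in gen_log) + "\n"
            )
            manifest.register(lpath)

            pretrained = None
            vocab_sources = [list(u.tokens) for u in corpus]
            if not config.skip_pretrain:
                adu = generate_adu_text(spec, config.n_adu_words, config.seed)
                vocab = make_vocab(adu + vocab_sources)
                pretrained = pretrain(adu, mconfig, vocab=vocab)

            log.info("cross-validating %s (k=%d)", spec.name, config.k_folds)
            result = kfold_evaluate(corpus, config.k_folds, mconfig, pretrained=pretrained)
            fpath = out / f"{spec.name}.folds.csv"
            result.fold_table.to_csv(fpath, index=False)
            manifest.register(fpath)

            records = []
            for u in corpus:
                records.extend(extract_records(result.trajectories[u.id], u))
            all_records.append(records_to_frame(records))

            stats = corpus_statistics(corpus)
            report["languages"][spec.name] = {
                "n_utterances": len(corpus),
                "entropy_bits": stats.entropy_bits,
                "role_proportions": {r.value: v for r, v in stats.role_proportions.items()},
                "mean_cv_accuracy": float(result.fold_table["accuracy"].mean()),
                "runtime_s": round(time.time() - t0, 1),
            }
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage failed for preset {spec.name!r}: {exc}"
            ) from exc

    records_df = pd.concat(all_records, ignore_index=True)
    rpath = out / "records.tsv"
    write_records(records_df, rpath)
    manifest.register(rpath)
    report["records_table_sha256"] = _sha256(rpath)

    if not config.skip_regression:
        log.info("fitting hierarchical beta regression")
        reg_kwargs = dict(config.regression)
        fixed_terms = reg_kwargs.pop(
            "fixed_terms",
            ["after_argument", "after_verb", "role", "language",
             "after_argument:after_verb:role:language"],
        )
        rspec = RegressionSpec(fixed_terms=fixed_terms, seed=config.seed, **reg_kwargs)
        design = build_design(records_df, rspec)
        try:
            fit = fit_beta_hierarchical(design, rspec)
            converged = fit.converged
        except ConvergenceError as err:
            raise RuntimeError(f"pipeline stage 'regress' failed: {err}") from err
        cells = [
            {"role": role, "after_argument": str(aa), "after_verb": str(av), "language": lang}
            for lang in design.factor_levels["language"]
            for role in design.factor_levels["role"]
            for aa in (False, True)
            for av in (False, True)
        ]
        cm = fit.cell_means(cells)
        cmpath = out / "cell_means.csv"
        cm.to_csv(cmpath, index=False)
        manifest.register(cmpath)
        contrast_cells = [
            {"role": role, "after_argument": str(aa), "after_verb": str(av)}
            for role in design.factor_levels["role"]
            for aa in (False, True)
            for av in (False, True)
        ]
        contrasts = pairwise_language_contrasts(fit, contrast_cells)
        ctpath = out / "contrasts.csv"
        contrasts.to_csv(ctpath, index=False)
        manifest.register(ctpath)
        dpath = out / "diagnostics.json"
        dpath.write_text(json.dumps({
            "converged": bool(converged),
            "phi_prior": fit.phi_prior,
            "max_rhat": float(fit.diagnostics["rhat"].max()),
            "min_ess_bulk": float(fit.diagnostics["ess_bulk"].min()),
            "min_ess_tail": float(fit.diagnostics["ess_tail"].min()),
        }, indent=2) + "\n")
        manifest.register(dpath)

    rppath = out / "report.json"
    rppath.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest.register(rppath)
    manifest.write()
    return out
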