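"""End-to-end orchestration: corpus -> summaries -> reliability -> keywords ->
platform comparison, bundled into files plus a Markdown report.

Stages that cannot run on the given input (e.g. keyword extraction on an
unlabeled corpus) are skipped with an explicit notice in the bundle rather
than aborting the run.  Logging goes to standard error; results only to files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import compare, corpus as corpus_mod, keywords as kw_mod
from .corpus import (
    Codebook,
    ContingencyTable,
    Corpus,
    default_codebook,
    read_codebook,
    read_corpus,
    select_top_by_reactions,
)
from .errors import VaxDiscourseError
from .preprocess import PreprocessConfig, load_stopwords, preprocess_corpus
from .reliability import AnnotationMatrix, krippendorff_alpha, read_annotations
from .synthetic import generate_annotations, generate_corpus, null_config, preset_platform_profiles

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """One run's inputs and knobs; serializes round-trip through YAML."""

    corpus_path: str | None = None
    corpus_format: str | None = None
    codebook_path: str | None = None
    annotations_path: str | None = None
    simulate_preset: str | None = None  # "null" or "distinct"
    n_top: int | None = 250
    stopwords_path: str | None = None
    lemmatizer: str = "english-suffix"
    translator: str = "identity"
    lam: float = 0.5
    top_n: int = 6
    alpha_level: float = 0.05
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        pre = raw.pop("preprocess", {})
        raw.setdefault("stopwords_path", pre.get("stopwords"))
        raw.setdefault("lemmatizer", pre.get("lemmatizer", "english-suffix"))
        raw.setdefault("translator", pre.get("translator", "identity"))
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All result surfaces of one run, plus skip notices and metadata."""

    config: RunConfig
    platform_summaries: list = field(default_factory=list)
    category_table: ContingencyTable | None = None
    anti_share: float | None = None
    reliability: Any = None
    keyword_lists: dict[int, list[str]] | None = None
    relevance_table: Any = None
    similarity: Any = None
    omnibus: Any = None
    pairwise: list | None = None
    skipped: dict[str, str] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)


def _preprocess_config(config: RunConfig) -> PreprocessConfig:
    if config.stopwords_path:
        stop = load_stopwords(config.stopwords_path)
        return PreprocessConfig(stop, config.lemmatizer, config.translator)
    return PreprocessConfig(
        lemmatizer=config.lemmatizer, translator=config.translator
    )


def _load_inputs(
    config: RunConfig,
) -> tuple[Corpus, Codebook, AnnotationMatrix | None]:
    codebook = (
        read_codebook(config.codebook_path)
        if config.codebook_path
        else default_codebook()
    )
    annotations = None
    if config.simulate_preset:
        maker = {"null": null_config, "distinct": preset_platform_profiles}.get(
            config.simulate_preset
        )
        if maker is None:
            raise VaxDiscourseError(
                f"unknown simulate preset {config.simulate_preset!r}"
            )
        sim = maker(seed=config.seed)
        corpus, truth = generate_corpus(sim)
        annotations = generate_annotations(truth, sim)
    elif config.corpus_path:
        corpus = read_corpus(config.corpus_path, config.corpus_format, codebook)  # type: ignore[arg-type]
        codebook = corpus.codebook
    else:
        raise VaxDiscourseError("config names neither a corpus path nor a preset")
    if config.annotations_path:
        annotations = read_annotations(config.annotations_path)
    return corpus, codebook, annotations


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all stages in order, recording skips instead of failing soft stages."""
    corpus, codebook, annotations = _load_inputs(config)
    bundle = ReportBundle(config=config)
    bundle.metadata = {"config_hash": config.config_hash(), "n_comments": len(corpus)}

    if config.n_top:
        corpus = select_top_by_reactions(corpus, config.n_top)
    bundle.platform_summaries = corpus_mod.summarize_platforms(corpus)

    if annotations is not None:
        bundle.reliability = krippendorff_alpha(annotations)
    else:
        bundle.skipped["reliability"] = "no annotations supplied"

    labeled = all(c.label is not None for c in corpus)
    if not labeled:
        bundle.skipped["categories"] = "corpus contains unlabeled comments"
        bundle.skipped["keywords"] = "label-dependent stage skipped"
        bundle.skipped["similarity"] = "label-dependent stage skipped"
        bundle.skipped["homogeneity"] = "label-dependent stage skipped"
        return bundle

    table = corpus_mod.tabulate_categories(corpus)
    bundle.category_table = table
    bundle.anti_share = corpus_mod.anti_vaccine_share(table, codebook)

    docs = preprocess_corpus(corpus, _preprocess_config(config))
    stats = kw_mod.compute_term_stats(docs)
    bundle.relevance_table = kw_mod.relevance_score(stats, config.lam)
    bundle.keyword_lists = kw_mod.rank_keywords(bundle.relevance_table, config.top_n)

    anti_table = table.subset(categories=list(codebook.anti_ids))
    try:
        dists = compare.anti_category_distributions(table, codebook)
        bundle.similarity = compare.similarity_matrix(dists)
    except VaxDiscourseError as exc:
        bundle.skipped["similarity"] = str(exc)
    try:
        pruned, removed = compare.prune_zero_expected(anti_table)
        bundle.omnibus = compare.chi_square_homogeneity(pruned, tuple(removed))
        bundle.pairwise = compare.pairwise_posthoc(anti_table, config.alpha_level)
    except VaxDiscourseError as exc:
        bundle.skipped["homogeneity"] = str(exc)
    return bundle


def homogeneity_payload(bundle: ReportBundle) -> dict[str, Any]:
    """JSON-ready omnibus + pairwise test results."""
    payload: dict[str, Any] = {}
    if bundle.omnibus is not None:
        payload["omnibus"] = {
            "chi2": bundle.omnibus.chi2,
            "df": bundle.omnibus.df,
            "p": bundle.omnibus.p,
            "removed": list(bundle.omnibus.removed_categories),
        }
    if bundle.pairwise is not None:
        payload["pairwise"] = [
            {
                "pair": list(r.pair),
                "chi2": r.chi2,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
                "removed": list(r.removed_categories),
                "error": r.error,
            }
            for r in bundle.pairwise
        ]
    return payload


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> None:
    """Write the machine-readable result files and the Markdown report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([vars(s) for s in bundle.platform_summaries]).to_csv(
        outdir / "platform_summaries.csv", index=False
    )
    if bundle.category_table is not None:
        bundle.category_table.counts.to_csv(outdir / "category_table.csv")
    if bundle.relevance_table is not None:
        kw_mod.write_keywords_tsv(
            bundle.relevance_table, outdir / "keywords.tsv", bundle.config.top_n
        )
    if bundle.similarity is not None:
        bundle.similarity.to_csv(outdir / "similarity.csv")
    payload = homogeneity_payload(bundle)
    if payload:
        (outdir / "homogeneity.json").write_text(
            json.dumps(payload, indent=2), encoding="utf-8"
        )
    (outdir / "metadata.json").write_text(
        json.dumps(
            {**bundle.metadata, "config": bundle.config.to_dict(),
             "skipped": bundle.skipped},
            indent=2,
        ),
        encoding="utf-8",
    )
    (outdir / "report.md").write_text(render_report(bundle), encoding="utf-8")


def render_report(bundle: ReportBundle) -> str:
    """Human-readable Markdown report mirroring the published table layouts."""
    lines = ["# Cross-platform vaccine-discourse analysis", ""]
    lines += ["## Platform overview", "",
              "| Platform | Comments | Sum of reactions | Mean length (words) |",
              "|---|---:|---:|---:|"]
    for s in bundle.platform_summaries:
        lines.append(
            f"| {s.platform} | {s.n_comments} | {s.sum_reactions} "
            f"| {s.mean_length_words:.1f} |"
        )
    lines.append("")

    if bundle.reliability is not None:
        lines += [
            "## Interrater reliability",
            "",
            f"Krippendorff's alpha (nominal) = {bundle.reliability.alpha:.3f} "
            f"on {bundle.reliability.n_items_used} double-coded items.",
            "",
            "For context: the original study reported alpha = 0.919 on its "
            "100-comment double-coded subsample (raw annotations not public, "
            "so that value is not recomputable here).",
            "",
        ]
    elif "reliability" in bundle.skipped:
        lines += ["## Interrater reliability", "",
                  f"Skipped: {bundle.skipped['reliability']}.", ""]

    if bundle.category_table is not None:
        lines += ["## Category counts", "",
                  "| Category | Count | Fraction |", "|---:|---:|---:|"]
        totals = bundle.category_table.row_totals
        fracs = bundle.category_table.fractions
        for k in bundle.category_table.categories:
            lines.append(f"| {k} | {int(totals.loc[k])} | {fracs.loc[k]:.3f} |")
        lines += ["",
                  f"Anti-vaccine share: {100 * bundle.anti_share:.1f}%", ""]
    elif "categories" in bundle.skipped:
        lines += ["## Category counts", "",
                  f"Skipped: {bundle.skipped['categories']}.", ""]

    lines.append("## Keywords by category")
    lines.append("")
    if bundle.keyword_lists:
        for k in sorted(bundle.keyword_lists):
            kws = ", ".join(bundle.keyword_lists[k]) or "(no scored terms)"
            lines.append(f"- category {k}: {kws}")
    else:
        lines.append(f"Skipped: {bundle.skipped.get('keywords', 'no keywords')}.")
    lines.append("")

    lines.append("## Platform similarity (cosine)")
    lines.append("")
    if bundle.similarity is not None:
        df = bundle.similarity.to_frame()
        lines.append("| | " + " | ".join(df.columns) + " |")
        lines.append("|---|" + "---|" * len(df.columns))
        for platform, row in df.iterrows():
            lines.append(
                f"| {platform} | " + " | ".join(f"{v:.3f}" for v in row) + " |"
            )
    else:
        lines.append(f"Skipped: {bundle.skipped.get('similarity', 'unavailable')}.")
    lines.append("")

    lines.append("## Homogeneity of anti-vaccine argument distributions")
    lines.append("")
    if bundle.omnibus is not None:
        rm = bundle.omnibus.removed_categories
        lines.append(
            f"Omnibus chi-square = {bundle.omnibus.chi2:.4g}, "
            f"df = {bundle.omnibus.df}, p = {bundle.omnibus.p:.4g}."
        )
        lines.append(
            "Categories removed by the zero-expected rule "
            f"(zero count on two or more platforms): {list(rm) if rm else 'none'}."
        )
        lines.append("")
        if bundle.pairwise:
            lines += ["| Pair | chi2 | df | p raw | p Bonferroni | significant |",
                      "|---|---:|---:|---:|---:|---|"]
            for r in bundle.pairwise:
                if r.error:
                    lines.append(f"| {r.pair[0]}-{r.pair[1]} | untestable: {r.error} |||||")
                else:
                    lines.append(
                        f"| {r.pair[0]}-{r.pair[1]} | {r.chi2:.4g} | {r.df} "
                        f"| {r.p_raw:.4g} | {r.p_adjusted:.4g} | {r.significant} |"
                    )
    else:
        lines.append(f"Skipped: {bundle.skipped.get('homogeneity', 'unavailable')}.")
    lines.append("")
    return "\n".join(lines)
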