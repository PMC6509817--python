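"""End-to-end orchestration and publication-style output tables.

``run_screen`` executes filter -> element annotation -> effect calling ->
lineage subtraction -> candidate selection, and collects every stage's
summary in a :class:`ScreenReport`.  ``render_tables`` writes the
cross-tabulation (per variant class x element, with the focal-unique
subset as a second column) and the candidate-gene table as TSV or
markdown.  The report is a pure function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__ as _version
from .effects import EffectSummary, call_effects, count_effects
from .elements import (
    ElementCrosstab,
    ElementIndex,
    build_element_index,
    classify_all,
    tabulate_elements,
)
from .errors import MutscreenError
from .formats import GeneModel, GenomeSequence, VariantRecord
from .hardfilter import FilterConfig, filter_pipeline, summarize_filter
from .lineage import (
    CandidateGene,
    Pedigree,
    StrainVariantSet,
    select_candidate_genes,
    unique_variants,
)


@dataclass
class ScreenReport:
    """Everything the screen computes, ready for rendering."""

    pedigree: Pedigree
    filter_summaries: dict[str, dict[str, int]]
    pass_sets: dict[str, list[VariantRecord]]
    unique: StrainVariantSet
    crosstab_all: ElementCrosstab
    crosstab_unique: ElementCrosstab
    effects_all: EffectSummary
    effects_unique: EffectSummary
    candidates: list[CandidateGene]
    provenance: dict = field(default_factory=dict)

    @property
    def n_candidate_genes(self) -> int:
        return len(self.candidates)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, MutscreenError):
                raise type(exc)(f"[stage {name}] {exc}") from exc
            return False

    return _Ctx()


def run_screen(
    genome: Sequence[GenomeSequence],
    models: Sequence[GeneModel],
    strain_variants: Mapping[str, Sequence[VariantRecord]],
    pedigree: Pedigree,
    filter_config: Optional[FilterConfig] = None,
    promoter_bp: int = 1000,
    terminator_bp: int = 500,
    element_index: Optional[ElementIndex] = None,
) -> ScreenReport:
    """Run the full screen over per-strain variant sets.

    Every strain is hard-filtered; the focal strain's passing set is
    annotated and effect-called; the unique subset (absent from every
    comparison strain, allele-exact after indel left-alignment) is
    re-annotated, and candidate genes are selected from it.
    """
    filter_config = filter_config or FilterConfig()

    filter_summaries: dict[str, dict[str, int]] = {}
    pass_sets: dict[str, list[VariantRecord]] = {}
    with _stage("filter"):
        for sid, records in strain_variants.items():
            passing, verdicts = filter_pipeline(list(records), filter_config)
            pass_sets[sid] = passing
            filter_summaries[sid] = summarize_filter(verdicts)

    with _stage("annotate"):
        index = element_index or build_element_index(
            models, genome, promoter_bp, terminator_bp
        )
        focal_pass = pass_sets[pedigree.focal]
        hits_all = classify_all(focal_pass, index)
        crosstab_all = tabulate_elements(hits_all, focal_pass)

    with _stage("effects"):
        calls_all = call_effects(hits_all, models, genome)
        effects_all = count_effects(calls_all)

    with _stage("lineage"):
        sets = [
            StrainVariantSet(sid, list(recs)) for sid, recs in pass_sets.items()
        ]
        unique = unique_variants(sets, pedigree, genome)
        unique_keys = unique.keys()
        hits_unique = [h for h in hits_all if h.variant.key in unique_keys]
        calls_unique = [c for c in calls_all if c.variant.key in unique_keys]
        crosstab_unique = tabulate_elements(hits_unique, unique.variants)
        effects_unique = count_effects(calls_unique)

    with _stage("candidates"):
        candidates = select_candidate_genes(unique, hits_unique, calls_unique, models)

    provenance = {
        "software": f"mutscreen {_version}",
        "focal": pedigree.focal,
        "comparison_strains": list(pedigree.comparison_strains),
        "promoter_bp": promoter_bp,
        "terminator_bp": terminator_bp,
        "n_input_variants": {s: len(v) for s, v in strain_variants.items()},
    }
    return ScreenReport(
        pedigree=pedigree,
        filter_summaries=filter_summaries,
        pass_sets=pass_sets,
        unique=unique,
        crosstab_all=crosstab_all,
        crosstab_unique=crosstab_unique,
        effects_all=effects_all,
        effects_unique=effects_unique,
        candidates=candidates,
        provenance=provenance,
    )


_ROW_LABELS = {
    "total": "Total {cls}s",
    "promoter": "In promoters",
    "terminator": "In terminators",
    "intron": "In introns",
    "exon": "In exons",
    "synonymous": "Synonymous",
    "nonsynonymous": "Nonsynonymous",
    "intergenic": "Total intergenic hits",
    "genes": "Number of genes affected",
}


def crosstab_table(report: ScreenReport) -> pd.DataFrame:
    """Long-form cross-tabulation: one block per variant class, with the
    full focal set and its unique subset side by side."""
    rows = []
    for cls, label in (("SNP", "SNP"), ("indel", "indel")):
        pairs = [
            ("total", report.crosstab_all.n_variants[cls],
             report.crosstab_unique.n_variants[cls]),
            ("promoter", report.crosstab_all.counts.loc["promoter", cls],
             report.crosstab_unique.counts.loc["promoter", cls]),
            ("terminator", report.crosstab_all.counts.loc["terminator", cls],
             report.crosstab_unique.counts.loc["terminator", cls]),
            ("intron", report.crosstab_all.counts.loc["intron", cls],
             report.crosstab_unique.counts.loc["intron", cls]),
            ("exon", report.crosstab_all.counts.loc["exon", cls],
             report.crosstab_unique.counts.loc["exon", cls]),
        ]
        if cls == "SNP":
            pairs += [
                ("synonymous", report.effects_all.n_synonymous,
                 report.effects_unique.n_synonymous),
                ("nonsynonymous", report.effects_all.n_nonsynonymous,
                 report.effects_unique.n_nonsynonymous),
            ]
        pairs += [
            ("intergenic", report.crosstab_all.intergenic[cls],
             report.crosstab_unique.intergenic[cls]),
            ("genes", report.crosstab_all.genes_affected[cls],
             report.crosstab_unique.genes_affected[cls]),
        ]
        for key, all_n, uniq_n in pairs:
            rows.append(
                {
                    "class": label,
                    "row": _ROW_LABELS[key].format(cls=label),
                    "all": int(all_n),
                    "unique": int(uniq_n),
                }
            )
    return pd.DataFrame(rows, columns=["class", "row", "all", "unique"])


def candidate_table(report: ScreenReport) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "annotation": c.annotation,
            "mutation_labels": "; ".join(c.mutations),
            "elements_hit": ",".join(sorted(c.elements_hit)),
            "n_unique_variants": c.n_unique_variants,
        }
        for c in report.candidates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "annotation",
            "mutation_labels",
            "elements_hit",
            "n_unique_variants",
        ],
    )


def render_tables(
    report: ScreenReport, out_dir: str | Path, format: str = "tsv"
) -> dict[str, Path]:
    """Write the cross-tab and candidate tables; returns paths written."""
    if format not in ("tsv", "markdown"):
        raise MutscreenError(f"unknown output format {format!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    xtab = crosstab_table(report)
    cand = candidate_table(report)
    paths: dict[str, Path] = {}
    if format == "tsv":
        paths["crosstab"] = out / "element_crosstab.tsv"
        xtab.to_csv(paths["crosstab"], sep="\t", index=False)
        paths["candidates"] = out / "candidate_genes.tsv"
        cand.to_csv(paths["candidates"], sep="\t", index=False)
    else:
        paths["crosstab"] = out / "element_crosstab.md"
        paths["crosstab"].write_text(xtab.to_markdown(index=False) + "\n")
        paths["candidates"] = out / "candidate_genes.md"
        paths["candidates"].write_text(cand.to_markdown(index=False) + "\n")
    return paths
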