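"""End-to-end orchestration: filter -> annotate -> DE -> compare -> enrich.

Each stage reads and writes only the documented plain-text formats, so
stages remain independently runnable; the orchestrator adds record-count
logging and conservation assertions between stages (annotation is total
over the transcript set, filtering only removes rows, every retained
transcript is tested once per contrast, Venn regions sum to the set
union). Outputs are deterministic: identical inputs give byte-identical
reports.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import io as mio
from .annotate import (
    AnnotationThresholds,
    TranscriptAnnotation,
    annotate_transcriptome,
    annotations_to_dataframe,
)
from .compare import (
    apply_ltm_filter,
    candidates_to_dataframe,
    compute_overlaps,
    summarize_gene_de,
    venn_to_dataframe,
)
from .de import DECall, build_design, calls_to_dataframe, dataframe_to_calls, estimate_dispersions, fit_and_test
from .enrich import enrichment_to_dataframe, fisher_enrichment, load_ontology, map_to_slim
from .filtering import exclude_transcripts, filter_low_support

logger = logging.getLogger("memorydiff.pipeline")


class PipelineError(RuntimeError):
    pass


@dataclass
class SpeciesInputs:
    label: str
    bundle_dir: str
    unconditioned_label: str = "unconditioned"

    def path(self, name: str) -> str:
        return os.path.join(self.bundle_dir, name)


@dataclass
class PipelineConfig:
    output_dir: str
    species: list[SpeciesInputs]
    arm_type: str = "Glo-ARM"
    ltm_types: list[str] = field(
        default_factory=lambda: ["Glo-LTM-short", "Glo-LTM-long", "Rub-LTM-long"]
    )
    splice_aware_types: list[str] = field(
        default_factory=lambda: ["Glo-LTM-short", "Glo-LTM-long"]
    )
    alpha: float = 0.05
    bh: bool = False
    cpm_threshold: float = 1.0
    min_samples: int = 3
    thresholds: AnnotationThresholds = field(default_factory=AnnotationThresholds)
    exclude_ids: str | None = None
    orthologs: str | None = None
    ontology: str | None = None
    annotations: str | None = None
    slim: str | None = None
    truth_bypass_de: bool = False


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["species"] = [SpeciesInputs(**s) for s in raw["species"]]
    if "thresholds" in raw:
        raw["thresholds"] = AnnotationThresholds(**raw["thresholds"])
    return PipelineConfig(**raw)


def _log_stage(stage: str, species: str, **counts) -> None:
    msg = ", ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("[%s] %s: %s", species, stage, msg)


@dataclass
class SpeciesResult:
    label: str
    annotations: list[TranscriptAnnotation]
    filtered_counts: pd.DataFrame
    calls: list[DECall]
    gene_map: dict[str, str]
    flagged: list[str]


def run_species(cfg: PipelineConfig, spec: SpeciesInputs, outdir: str) -> SpeciesResult:
    os.makedirs(outdir, exist_ok=True)
    try:
        counts = mio.read_counts(spec.path("counts.tsv"))
        meta = mio.read_tsv(spec.path("samples.tsv"), dtype=str)
        hits = mio.read_hits(spec.path("hits.tsv"))
        gene_map = mio.read_gene_map(spec.path("genes.tsv"))
        seqs = mio.read_fasta(spec.path("transcripts.fasta"))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[{spec.label}] input loading failed: {exc}") from exc

    lengths = {t: len(s) for t, s in seqs.items()}
    n_in = counts.shape[0]
    try:
        if cfg.exclude_ids:
            with open(cfg.exclude_ids) as fh:
                excl = {line.strip() for line in fh if line.strip()}
            counts = exclude_transcripts(counts, excl)
        filtered = filter_low_support(counts, cfg.cpm_threshold, cfg.min_samples)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[{spec.label}] filter stage failed: {exc}") from exc
    if not set(filtered.index) <= set(counts.index) or list(filtered.columns) != list(counts.columns):
        raise PipelineError(f"[{spec.label}] filter broke row/column conservation")
    _log_stage("filter", spec.label, transcripts_in=n_in, transcripts_kept=filtered.shape[0])
    mio.write_counts(filtered, os.path.join(outdir, "filtered_counts.tsv"))

    try:
        annotations = annotate_transcriptome(
            hits, gene_map, cfg.thresholds, transcript_lengths=lengths, sequences=seqs
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[{spec.label}] annotation stage failed: {exc}") from exc
    if len(annotations) != len(gene_map):
        raise PipelineError(f"[{spec.label}] annotation is not total over the gene map")
    _log_stage("annotate", spec.label, transcripts=len(annotations))
    mio.write_tsv(
        annotations_to_dataframe(annotations), os.path.join(outdir, "annotations.tsv")
    )

    try:
        if cfg.truth_bypass_de:
            truth_df = mio.read_tsv(spec.path("truth.tsv"))
            calls = _calls_from_truth(truth_df)
            flagged: list[str] = []
        else:
            design = build_design(meta, unconditioned_label=spec.unconditioned_label)
            dispersions = estimate_dispersions(filtered, design)
            calls, flagged = fit_and_test(
                filtered, design, dispersions, alpha=cfg.alpha, bh=cfg.bh
            )
            n_expected = (filtered.shape[0] - len(flagged)) * len(design.contrasts)
            if len(calls) != n_expected:
                raise PipelineError(
                    f"[{spec.label}] DE call count {len(calls)} != expected {n_expected}"
                )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[{spec.label}] DE stage failed: {exc}") from exc
    _log_stage("de", spec.label, calls=len(calls), flagged=len(flagged))
    mio.write_tsv(calls_to_dataframe(calls), os.path.join(outdir, "de_calls.tsv"))
    return SpeciesResult(
        label=spec.label,
        annotations=annotations,
        filtered_counts=filtered,
        calls=calls,
        gene_map=gene_map,
        flagged=flagged,
    )


def _calls_from_truth(truth_df: pd.DataFrame) -> list[DECall]:
    calls = []
    lfc_cols = [c for c in truth_df.columns if c.startswith("lfc_")]
    tids = truth_df["transcript_id"].astype(str).to_numpy()
    for col in lfc_cols:
        ct, tp = col[len("lfc_") :].split("@")
        vals = truth_df[col].astype(float).to_numpy()
        for tid, lf in zip(tids, vals):
            if lf != 0.0:
                calls.append(
                    DECall(
                        transcript_id=tid,
                        conditioning_type=ct,
                        time_point=tp,
                        logfc=float(lf),
                        p_value=0.0,
                        direction="up" if lf > 0 else "down",
                        significant=True,
                    )
                )
    return calls


def report_fractions(
    annotations: Sequence[TranscriptAnnotation], calls: Sequence[DECall]
) -> dict[str, pd.DataFrame]:
    """Summary tables: structural-class fractions over all and over DE
    transcripts, and per conditioning type a three-set time-point Venn
    of up- and downregulated transcripts."""
    classes = ["sense", "antisense", "lncRNA", "unknown"]
    by_class = {c: 0 for c in classes}
    for a in annotations:
        by_class[a.structural_class] += 1
    total = len(annotations)
    de_tx = {c.transcript_id for c in calls if c.significant}
    class_of = {a.transcript_id: a.structural_class for a in annotations}
    de_by_class = {c: 0 for c in classes}
    for t in de_tx:
        if t in class_of:
            de_by_class[class_of[t]] += 1
    rows = []
    for c in classes:
        rows.append(
            {
                "structural_class": c,
                "n_all": by_class[c],
                "fraction_all": by_class[c] / total if total else 0.0,
                "n_de": de_by_class[c],
                "fraction_de": de_by_class[c] / len(de_tx) if de_tx else 0.0,
            }
        )
    fractions = pd.DataFrame(rows)
    if de_tx == set():
        fractions.attrs["de_denominator_zero"] = True

    venn_rows = []
    by_type_dir: dict[tuple[str, str], dict[str, set[str]]] = {}
    for c in calls:
        if not c.significant:
            continue
        key = (c.conditioning_type, c.direction)
        by_type_dir.setdefault(key, {}).setdefault(c.time_point, set()).add(
            c.transcript_id
        )
    for (ct, direction), sets in sorted(by_type_dir.items()):
        venn = compute_overlaps(sets)
        union_n = len(set().union(*sets.values()))
        if venn.total() != union_n:
            raise PipelineError(
                f"Venn region sum {venn.total()} != union size {union_n} for {ct}"
            )
        for region, n in sorted(venn.regions.items(), key=lambda kv: sorted(kv[0])):
            venn_rows.append(
                {
                    "conditioning_type": ct,
                    "direction": direction,
                    "region": "&".join(sorted(region)),
                    "count": n,
                }
            )
    venn_df = pd.DataFrame(
        venn_rows, columns=["conditioning_type", "direction", "region", "count"]
    )
    return {"class_fractions": fractions, "timepoint_venn": venn_df}


def antisense_zone_table(annotations: Sequence[TranscriptAnnotation]) -> pd.DataFrame:
    """Figure-style antisense summary: link types and UTR-zone sets."""
    link_counts = {"antisense_to_protein_only": 0, "antisense_to_sense_only": 0, "both": 0}
    zone_counts: dict[str, int] = {}
    for a in annotations:
        if a.structural_class != "antisense":
            continue
        if a.antisense_to_protein and a.antisense_to_sense:
            link_counts["both"] += 1
        elif a.antisense_to_protein:
            link_counts["antisense_to_protein_only"] += 1
        else:
            link_counts["antisense_to_sense_only"] += 1
        if a.zone_set:
            key = "&".join(sorted(a.zone_set))
            zone_counts[key] = zone_counts.get(key, 0) + 1
    rows = [{"category": k, "count": v} for k, v in sorted(link_counts.items())]
    rows += [{"category": f"zones:{k}", "count": v} for k, v in sorted(zone_counts.items())]
    return pd.DataFrame(rows, columns=["category", "count"])


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and emit the report bundle; returns the run
    summary (also written as run_summary.json)."""
    os.makedirs(cfg.output_dir, exist_ok=True)
    summary: dict = {"species": {}, "stages": []}

    results: list[SpeciesResult] = []
    for spec in cfg.species:
        outdir = os.path.join(cfg.output_dir, spec.label)
        res = run_species(cfg, spec, outdir)
        results.append(res)
        reports = report_fractions(res.annotations, res.calls)
        frac = reports["class_fractions"]
        if abs(frac["fraction_all"].sum() - 1.0) > 1e-9:
            raise PipelineError(f"[{spec.label}] class fractions do not sum to 1")
        mio.write_tsv(frac, os.path.join(outdir, "class_fractions.tsv"))
        mio.write_tsv(reports["timepoint_venn"], os.path.join(outdir, "timepoint_venn.tsv"))
        mio.write_tsv(
            antisense_zone_table(res.annotations),
            os.path.join(outdir, "antisense_zones.tsv"),
        )
        summary["species"][spec.label] = {
            "transcripts": len(res.annotations),
            "filtered_transcripts": int(res.filtered_counts.shape[0]),
            "de_calls": len(res.calls),
            "significant_calls": sum(c.significant for c in res.calls),
            "flagged_transcripts": len(res.flagged),
        }

    # comparison stage over the union of species, through orthologs if given
    try:
        ortho = mio.read_ortholog_map(cfg.orthologs) if cfg.orthologs else {}
        all_calls: list[DECall] = []
        gene_map: dict[str, str] = {}
        for res in results:
            all_calls.extend(res.calls)
            for t, g in res.gene_map.items():
                gene_map[t] = ortho.get(g, g)
        summaries = summarize_gene_de(all_calls, gene_map)
        present_types = {c.conditioning_type for c in all_calls if c.significant}
        ltm_types = [t for t in cfg.ltm_types if t in present_types] or cfg.ltm_types
        candidates = apply_ltm_filter(
            summaries, ltm_types, cfg.arm_type, splice_aware_types=cfg.splice_aware_types
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"compare stage failed: {exc}") from exc
    _log_stage("compare", "all", genes=len(summaries), candidates=len(candidates))
    mio.write_tsv(
        candidates_to_dataframe(candidates), os.path.join(cfg.output_dir, "candidates.tsv")
    )
    summary["candidates"] = len(candidates)

    if len(results) > 1 and ortho:
        de_gene_sets = {}
        for res in results:
            de_gene_sets[res.label] = {
                gene_map[c.transcript_id]
                for c in res.calls
                if c.significant and c.transcript_id in gene_map
            }
        venn = compute_overlaps(de_gene_sets)
        mio.write_tsv(
            venn_to_dataframe(venn),
            os.path.join(cfg.output_dir, "interspecific_venn.tsv"),
        )
        summary["interspecific_de_overlap"] = {
            "&".join(sorted(k)): v for k, v in venn.regions.items()
        }

    # enrichment stage (needs ontology inputs)
    if cfg.ontology and cfg.annotations and cfg.slim:
        try:
            with open(cfg.slim) as fh:
                slim_terms = [line.strip() for line in fh if line.strip()]
            ontology = load_ontology(cfg.ontology, slim_terms)
            gene_terms = mio.read_annotations_tsv(cfg.annotations)
            if ortho:
                projected: dict[str, set[str]] = {}
                for g, terms in gene_terms.items():
                    projected.setdefault(ortho.get(g, g), set()).update(terms)
                gene_terms = projected
            slim_annotations = map_to_slim(gene_terms, ontology)
            enrich_frames = []
            for res in results:
                population = {
                    gene_map.get(t, res.gene_map[t]) for t in res.filtered_counts.index
                } & set(slim_annotations)
                strata: dict[tuple[str, str, str], set[str]] = {}
                for c in res.calls:
                    if not c.significant:
                        continue
                    g = gene_map.get(c.transcript_id)
                    if g in population:
                        strata.setdefault(
                            (c.conditioning_type, c.time_point, c.direction), set()
                        ).add(g)
                for (ct, tp, direction), study in sorted(strata.items()):
                    enr = fisher_enrichment(study, population, slim_annotations, cfg.alpha)
                    enrich_frames.append(
                        enrichment_to_dataframe(
                            enr,
                            species=res.label,
                            conditioning_type=ct,
                            time_point=tp,
                            direction=direction,
                        )
                    )
            enr_df = (
                pd.concat(enrich_frames, ignore_index=True)
                if enrich_frames
                else pd.DataFrame()
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"enrich stage failed: {exc}") from exc
        mio.write_tsv(enr_df, os.path.join(cfg.output_dir, "enrichment.tsv"))
        summary["enrichment_rows"] = int(enr_df.shape[0])

    with open(os.path.join(cfg.output_dir, "run_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
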