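"""End-to-end orchestration: simulate -> score -> effects -> summarize ->
enrich -> survive, with a manifest recording seeds, digests and row counts.

Stages are plain library calls writing plain files into a run directory;
each is also importable on its own. Rerunning with an identical config and
inputs reproduces identical outputs (all stochastic stages are seeded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .cohort_stats import (
    cancer_summary_frame,
    gene_level_stats,
    gene_summary_frame,
    summarize_by_cancer,
    top_mutations,
)
from .enrichment import enrichment_frame, fisher_enrichment
from .errors import InputError, PsdeltaError, ValidationError
from .io_formats import (
    read_clinical_table,
    read_fasta,
    read_gmt,
    read_mutation_table,
    write_clinical_table,
    write_effects_table,
    write_fasta,
    write_gmt,
    write_mutation_table,
)
from .mutation_effect import EffectConfig, delta_ps_batch
from .ps_scoring import ScorerSpec, call_ps_regions, score_windows
from .survival import (
    SurvivalConfig,
    fit_cox,
    median_split_km,
    patient_variables,
    vars_frame,
)
from .synthetic_data import (
    DEFAULT_CANCER_TYPES,
    generate_annotations,
    generate_cohort,
    generate_mutations,
    generate_proteome,
    true_percent_mut,
)

logger = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    """Parameters of the default synthetic scenario.

    The class mix plants roughly 10% PS-affecting mutations with the
    negative class outnumbering the positive one, the affecting-fraction
    regime a pan-cancer missense cohort shows; segment rate and prone
    probabilities put ~70% of proteins in the phase-separating class.
    """

    n_proteins: int = 200
    length_range: tuple[int, int] = (80, 250)
    segment_rate: float = 0.7
    prone_in: float = 0.9
    prone_out: float = 0.1
    n_mutations: int = 2000
    class_mix: tuple[float, float, float] = (0.04, 0.06, 0.90)
    n_samples: int = 240
    cancer_types: tuple[str, ...] = DEFAULT_CANCER_TYPES
    n_sets: int = 50
    planted_set_ids: tuple[str, ...] = ("SET00", "SET01", "SET02")
    relative_risk: float = 5.0
    beta: float = 1.0
    baseline_hazard: float = 0.001
    censor_rate: float = 0.3


@dataclass
class RunConfig:
    """All paths and knobs for one pipeline run."""

    out_dir: str = "psdelta_run"
    seed: int = 0
    simulate: bool = True
    fasta: str | None = None
    mutations: str | None = None
    gmt: str | None = None
    clinical: str | None = None
    effect: EffectConfig = field(default_factory=EffectConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    top_n: int = 10
    ps_variable: str = "percent_mut"
    enrichment_alternative: str = "greater"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        with path.open() as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "effect" in kwargs:
            kwargs["effect"] = EffectConfig(**kwargs["effect"])
        if "survival" in kwargs:
            kwargs["survival"] = SurvivalConfig(**kwargs["survival"])
        if "scenario" in kwargs:
            sc = dict(kwargs["scenario"])
            for key in ("length_range", "class_mix", "cancer_types", "planted_set_ids"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            kwargs["scenario"] = ScenarioConfig(**sc)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_inputs(config: RunConfig, input_dir: Path) -> dict:
    """Generate the synthetic scenario into ``input_dir``; returns row counts."""
    sc = config.scenario
    input_dir.mkdir(parents=True, exist_ok=True)

    proteome, truth = generate_proteome(
        n_proteins=sc.n_proteins,
        length_range=sc.length_range,
        segment_rate=sc.segment_rate,
        prone_in=sc.prone_in,
        prone_out=sc.prone_out,
        seed=config.seed,
    )
    write_fasta(proteome, input_dir / "proteome.fasta")

    mutations, truth = generate_mutations(
        proteome,
        truth,
        n_mutations=sc.n_mutations,
        class_mix=sc.class_mix,
        seed=config.seed + 1,
        n_samples=sc.n_samples,
        cancer_types=sc.cancer_types,
        window_size=config.effect.window_size,
        affect_cutoff=config.effect.affect_cutoff,
    )
    write_mutation_table(mutations, input_dir / "mutations.tsv")

    genes = sorted({m.gene for m in mutations})
    affected_genes = sorted(
        {m.gene for m, cls in zip(mutations, truth.mutation_classes) if cls != "neutral"}
    )
    annotations, ann_truth = generate_annotations(
        genes,
        n_sets=sc.n_sets,
        planted_ids=sc.planted_set_ids,
        relative_risk=sc.relative_risk,
        seed=config.seed + 2,
        target_genes=affected_genes,
    )
    truth = truth.merged(ann_truth)
    write_gmt(annotations, input_dir / "annotations.gmt")

    assignment: dict[str, list[str]] = {}
    for m, cls in zip(mutations, truth.mutation_classes):
        assignment.setdefault(m.sample_id, []).append(cls)
    sample_ids = [f"SAMPLE{j:04d}" for j in range(sc.n_samples)]
    clinical, cohort_truth = generate_cohort(
        sample_ids,
        mutation_assignment=assignment,
        beta=sc.beta,
        baseline_hazard=sc.baseline_hazard,
        censor_rate=sc.censor_rate,
        seed=config.seed + 3,
        cancer_types=sc.cancer_types,
    )
    truth = truth.merged(cohort_truth)
    write_clinical_table(clinical, input_dir / "clinical.tsv")
    truth.to_json(input_dir / "truth.json")
    return {
        "proteins": len(proteome),
        "mutations": len(mutations),
        "annotation_sets": len(annotations),
        "clinical_samples": len(clinical),
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage error aborts with the failing stage named in the raised
    exception; the manifest is written only on success.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "stages": {},
        "inputs": {},
    }

    def stage(name):
        logger.info("stage: %s", name)

    # ---- simulate / load inputs
    input_dir = out / "inputs"
    try:
        if config.simulate:
            stage("simulate")
            counts = simulate_inputs(config, input_dir)
            manifest["stages"]["simulate"] = counts
            fasta_path = input_dir / "proteome.fasta"
            mut_path = input_dir / "mutations.tsv"
            gmt_path = input_dir / "annotations.gmt"
            clin_path = input_dir / "clinical.tsv"
        else:
            for name, p in (
                ("fasta", config.fasta),
                ("mutations", config.mutations),
                ("gmt", config.gmt),
                ("clinical", config.clinical),
            ):
                if p is None or not Path(p).exists():
                    raise InputError(f"stage load: missing input path for {name}: {p}")
            fasta_path, mut_path = Path(config.fasta), Path(config.mutations)
            gmt_path, clin_path = Path(config.gmt), Path(config.clinical)

        for p in (fasta_path, mut_path, gmt_path, clin_path):
            manifest["inputs"][p.name] = _sha256(p)

        proteins = {p.accession: p for p in read_fasta(fasta_path)}
        mutations = read_mutation_table(mut_path)
        annotations = read_gmt(gmt_path)
        clinical = read_clinical_table(clin_path)

        # ---- score
        stage("score")
        spec = config.effect.scorer_spec()
        tracks = {acc: score_windows(p, spec) for acc, p in proteins.items()}
        regions = {
            acc: call_ps_regions(t, config.effect.region_cutoff)
            for acc, t in tracks.items()
        }
        score_rows = [
            {"accession": acc, "start": int(s), "score": float(v)}
            for acc, t in sorted(tracks.items())
            for s, v in zip(t.starts, t.scores)
        ]
        pd.DataFrame(score_rows).to_csv(out / "window_scores.tsv", sep="\t", index=False)
        region_rows = [
            {
                "accession": acc,
                "start": r.start,
                "end": r.end,
                "mean_score": round(r.mean_score, 6),
            }
            for acc, rs in sorted(regions.items())
            for r in rs
        ]
        pd.DataFrame(
            region_rows, columns=["accession", "start", "end", "mean_score"]
        ).to_csv(out / "ps_regions.tsv", sep="\t", index=False)
        manifest["stages"]["score"] = {
            "windows": len(score_rows),
            "regions": len(region_rows),
            "ps_proteins": sum(bool(r) for r in regions.values()),
        }

        # ---- effects
        stage("effects")
        effects = delta_ps_batch(proteins, mutations, config.effect)
        write_effects_table(effects, out / "effects.tsv")
        manifest["stages"]["effects"] = {
            "mutations_in": len(mutations),
            "effects_rows": len(effects),
        }

        # ---- summarize
        stage("summarize")
        cancer = summarize_by_cancer(effects, regions)
        genes = gene_level_stats(effects, regions)
        top = top_mutations(effects, config.top_n)
        cancer_summary_frame(cancer).to_csv(out / "cancer_summary.tsv", sep="\t", index=False)
        gene_summary_frame(genes).to_csv(out / "gene_summary.tsv", sep="\t", index=False)
        write_effects_table(top, out / "top_mutations.tsv")
        report = {
            "n_effects": len(effects),
            "n_positive": sum(e.affect_label == "positive" for e in effects),
            "n_negative": sum(e.affect_label == "negative" for e in effects),
            "n_aberrant": sum(e.aberrant_label != "none" for e in effects),
            "n_on_ps_region": sum(e.on_ps_region for e in effects),
            "n_cancer_types": len(cancer),
            "n_genes": len(genes),
            "n_ps_genes": sum(g.is_ps_protein for g in genes),
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        manifest["stages"]["summarize"] = report

        # ---- enrich
        stage("enrich")
        universe = sorted({e.mutation.gene for e in effects})
        target = sorted(
            {e.mutation.gene for e in effects if e.affect_label != "neutral"}
        )
        results = fisher_enrichment(
            target, universe, annotations, alternative=config.enrichment_alternative
        )
        enrichment_frame(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["enrich"] = {
            "sets_tested": len(results),
            "sets_q_lt_0.05": sum(r.q_value < 0.05 for r in results),
        }

        # ---- survive
        stage("survive")
        pvars = patient_variables(effects, clinical, config.survival)
        df = vars_frame(pvars)
        df.to_csv(out / "patient_variables.tsv", sep="\t", index=False)
        cox_rows, km_rows, lr_rows = [], [], []
        for cancer_type, sub in df.groupby("cancer_type"):
            try:
                fit = fit_cox(sub, ps_variable=config.ps_variable)
                for v in fit.variables:
                    cox_rows.append(
                        {
                            "cancer_type": cancer_type,
                            "variable": v,
                            "coef": fit.coefficients[v],
                            "se": fit.standard_errors[v],
                            "p": fit.p_values[v],
                            "n_subjects": fit.n_subjects,
                            "n_events": fit.n_events,
                        }
                    )
                km = median_split_km(sub, config.ps_variable)
                lr_rows.append(
                    {
                        "cancer_type": cancer_type,
                        "variable": config.ps_variable,
                        "logrank_statistic": km.statistic,
                        "logrank_p": km.p_value,
                        "median_cutoff": km.median_cutoff,
                    }
                )
                for grp, curve in km.curves.items():
                    for _, row in curve.iterrows():
                        km_rows.append(
                            {
                                "cancer_type": cancer_type,
                                "group": grp,
                                "time": row["time"],
                                "survival": row["survival"],
                            }
                        )
            except PsdeltaError as exc:
                logger.warning("survival analysis failed for %s: %s", cancer_type, exc)
                lr_rows.append(
                    {
                        "cancer_type": cancer_type,
                        "variable": config.ps_variable,
                        "logrank_statistic": float("nan"),
                        "logrank_p": float("nan"),
                        "median_cutoff": float("nan"),
                    }
                )
        pd.DataFrame(
            cox_rows,
            columns=["cancer_type", "variable", "coef", "se", "p", "n_subjects", "n_events"],
        ).to_csv(out / "cox_fits.tsv", sep="\t", index=False)
        pd.DataFrame(
            km_rows, columns=["cancer_type", "group", "time", "survival"]
        ).to_csv(out / "km_curves.tsv", sep="\t", index=False)
        pd.DataFrame(
            lr_rows,
            columns=["cancer_type", "variable", "logrank_statistic", "logrank_p", "median_cutoff"],
        ).to_csv(out / "logrank.tsv", sep="\t", index=False)
        manifest["stages"]["survive"] = {
            "patients": len(pvars),
            "cox_rows": len(cox_rows),
            "cancers_fit": len({r["cancer_type"] for r in cox_rows}),
        }
    except PsdeltaError:
        raise
    except Exception as exc:  # wrap non-package failures with stage context
        raise PsdeltaError(f"pipeline failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
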