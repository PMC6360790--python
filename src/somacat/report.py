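"""Cohort-level reporting: group comparisons and pipeline orchestration.

Group comparisons (one-way ANOVA with Tukey HSD post-hoc) are reporting
only — they never gate pipeline behaviour.  ``run_pipeline`` chains the
stages over a config mapping of per-stage input files; stages whose
inputs are absent are skipped with a warning and noted in the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    """One-way ANOVA plus pairwise Tukey HSD adjusted p-values."""

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject


def group_compare(values: Sequence[float], groups: Sequence[str]) -> GroupComparison:
    """Compare a per-sample quantity across >= 2 labelled groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must align")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    per_group = [values[groups == g] for g in labels]
    if any(len(g) < 1 for g in per_group):
        raise ValueError("every group needs at least one sample")
    f, p = stats.f_oneway(*per_group)
    tk = pairwise_tukeyhsd(values, groups)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return GroupComparison(f_statistic=float(f), p_value=float(p), tukey=tukey)


#: Every study-derived constant, surfaced so deviations are explicit.
DEFAULT_CONFIG: dict = {
    "signatures": {"k": 5, "n_restarts": 200, "seed": 0, "prune_threshold": 0.10},
    "kataegis": {"gamma": 12.0, "kmin": 2, "min_mutations": 6, "max_mean_imd": 1000.0},
    "rearrangements": {"window": 1_000_000, "min_count": 10, "min_sv": 10, "k": 4},
    "cnv": {"ploidy_cutoff": 2.7, "amp_cn_diploid": 6, "amp_cn_duplicated": 9,
            "deletion_rule": "results"},
    "telomere": {"motif": "TTAGGG", "min_copies": 3},
    "overlap": {"min_coverage": 10, "min_mapping_quality": 10,
                "min_aligned_bases": 34, "max_mismatches": 3},
}


def run_pipeline(config: Mapping, out_dir) -> dict[str, object]:
    """Run the configured stages end to end over file inputs.

    ``config`` maps stage names to input paths and parameters (see
    :data:`DEFAULT_CONFIG` for the parameter defaults).  Returns a report
    dict with per-stage outputs and a ``skipped`` list; deterministic for
    a fixed seed.
    """
    from . import catalogue as cat
    from . import cnv as cnvmod
    from . import complex_events as cx
    from . import io as sio
    from . import kataegis as kat
    from . import rearrangements as rea
    from . import signatures as sig
    from . import telomere as tel
    from . import overlap as ovl

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {k: {**v} for k, v in DEFAULT_CONFIG.items()}
    for stage, overrides in config.get("parameters", {}).items():
        params.setdefault(stage, {}).update(overrides)
    inputs = config.get("inputs", {})
    report: dict[str, object] = {"skipped": []}

    def skip(stage: str, why: str) -> None:
        logger.warning("stage %s skipped: %s", stage, why)
        report["skipped"].append({"stage": stage, "reason": why})

    records = None
    if "mutations" in inputs:
        records = sio.read_mutation_table(inputs["mutations"])
    else:
        skip("catalogue", "no mutation table configured")

    catalogue_matrix = None
    if records is not None:
        build = cat.build_catalogues(records)
        catalogue_matrix = build.as_frame()
        cat.write_catalogue_matrix(build, out / "catalogues.tsv")
        report["catalogue"] = {"n_samples": len(build.catalogues),
                               "n_skipped_records": len(build.skipped)}
    if "catalogues" in inputs:  # precomputed matrix takes precedence
        catalogue_matrix = cat.read_catalogue_matrix(inputs["catalogues"])

    if catalogue_matrix is not None and catalogue_matrix.shape[1] >= 2:
        p = params["signatures"]
        model = sig.extract_signatures(catalogue_matrix, k=min(p["k"], catalogue_matrix.shape[1]),
                                       n_restarts=p["n_restarts"], seed=p["seed"])
        exposures = sig.refit_cohort(catalogue_matrix, model.signatures,
                                     prune_threshold=p["prune_threshold"])
        model.signatures_frame().to_csv(out / "signatures.tsv", sep="\t", index_label="class")
        pd.DataFrame(exposures, index=list(model.signature_ids),
                     columns=list(catalogue_matrix.columns)).to_csv(
            out / "exposures.tsv", sep="\t", index_label="signature")
        report["signatures"] = {"k": model.k, "reconstruction_error": model.reconstruction_error}
    elif catalogue_matrix is not None:
        skip("signatures", "fewer than 2 samples")

    if records is not None:
        p = params["kataegis"]
        regions = kat.call_kataegis(records, gamma=p["gamma"], kmin=p["kmin"],
                                    min_mutations=p["min_mutations"],
                                    max_mean_imd=p["max_mean_imd"])
        kat.regions_to_bed(regions).to_csv(out / "kataegis.tsv", sep="\t", index=False)
        report["kataegis"] = {"n_regions": len(regions)}

    events_by_sample: dict[str, list] = {}
    if "svs" in inputs:
        p = params["rearrangements"]
        frame = sio.read_bedpe(inputs["svs"])
        for sid, group in frame.groupby("sample_id"):
            evs = rea.events_from_frame(group)
            events_by_sample[str(sid)] = rea.cluster_breakpoints(
                evs, window=p["window"], min_count=p["min_count"])
        cats = [rea.build_rearrangement_catalogue(v, k) for k, v in events_by_sample.items()]
        rea.catalogue_matrix(cats).to_csv(out / "rearrangement_catalogues.tsv", sep="\t",
                                          index_label="class")
        report["rearrangements"] = {"n_samples": len(cats),
                                    "n_events": int(sum(c.total for c in cats))}
    else:
        skip("rearrangements", "no BEDPE configured")

    profiles = {}
    if "segments" in inputs and "ploidy" in inputs:
        p = params["cnv"]
        segments = sio.read_segments(inputs["segments"])
        ploidies = sio.read_ploidy_table(inputs["ploidy"])
        profiles = cnvmod.profiles_from_frame(segments, ploidies)
        frames = [cnvmod.call_events(pr) for pr in profiles.values()]
        pd.concat(frames, ignore_index=True).to_csv(out / "cn_events.tsv", sep="\t", index=False)
        if "chrom_sizes" in inputs:
            genome = sum(sio.read_chrom_sizes(inputs["chrom_sizes"]).values())
            fractions = {sid: cnvmod.genome_fraction_altered(pr, genome, p["deletion_rule"])
                         for sid, pr in profiles.items()}
            report["cnv"] = {"genome_fraction_altered": fractions}
        if "genes" in inputs:
            genes = sio.read_bed(inputs["genes"])
            gene_frames = [cnvmod.annotate_genes(pr, genes).assign(sample_id=sid)
                           for sid, pr in profiles.items()]
            pd.concat(gene_frames, ignore_index=True).to_csv(out / "gene_cn.tsv", sep="\t",
                                                             index=False)
    else:
        skip("cnv", "segments/ploidy inputs not configured")

    if profiles and events_by_sample:
        sizes = sio.read_chrom_sizes(inputs["chrom_sizes"]) if "chrom_sizes" in inputs else None
        all_reports = []
        for sid, profile in profiles.items():
            evs = events_by_sample.get(sid, [])
            all_reports += cx.detect_complex_events(evs, profile, chrom_sizes=sizes)
        cx.reports_to_frame(all_reports).to_csv(out / "complex_events.tsv", sep="\t", index=False)
        report["complex_events"] = {
            "n_flagged": int(sum(1 for r in all_reports if r.flags))}
    else:
        skip("complex_events", "needs both CN profiles and SV events")

    if "telomere" in inputs:
        table = sio.read_telomere_table(inputs["telomere"])
        rows = []
        for r in table.itertuples(index=False):
            t = tel.TelomereInput(str(getattr(r, "pair_id", getattr(r, "sample_id", "pair"))),
                                  int(r.tumour_count), float(r.tumour_coverage))
            n = tel.TelomereInput(t.sample_id + "_N", int(r.normal_count), float(r.normal_coverage))
            rows.append({"pair_id": t.sample_id, "log2_ratio": tel.telomere_ratio(t, n)})
        pd.DataFrame(rows).to_csv(out / "telomere_ratios.tsv", sep="\t", index=False)
        report["telomere"] = {"n_pairs": len(rows)}
    else:
        skip("telomere", "no telomere table configured")

    if "pileup_a" in inputs and "pileup_b" in inputs:
        p = params["overlap"]

        def load(path):
            df = sio.read_pileup_table(path)
            ev = {(r.chrom, int(r.pos)): ovl.PileupEvidence(
                chrom=str(r.chrom), pos=int(r.pos), coverage=int(r.coverage),
                good_alt_reads=int(r.good_alt_reads), normal_alt_reads=int(r.normal_alt_reads))
                for r in df.itertuples(index=False)}
            calls = [(r.chrom, int(r.pos)) for r in df.itertuples(index=False)
                     if bool(getattr(r, "called", True))]
            return calls, ev

        calls_a, ev_a = load(inputs["pileup_a"])
        calls_b, ev_b = load(inputs["pileup_b"])
        result = ovl.overlap_fraction(calls_a, calls_b, ev_a, ev_b,
                                      min_coverage=p["min_coverage"])
        report["overlap"] = {
            "union_fraction": result.union_fraction,
            "fraction_a_in_b": result.fraction_a_in_b,
            "fraction_b_in_a": result.fraction_b_in_a,
            "n_union": result.n_union,
        }
    else:
        skip("overlap", "paired pileup tables not configured")

    return report
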