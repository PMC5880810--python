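"""End-to-end flows behind the command line: annotate and qPCR.

``annotate_records`` runs the full sequence-characterisation chain per
query: NPA scan, hydropathy topology, reference anchoring and residue
extraction, residue-rule classification, SSSS/SDP substrate verdicts
with consensus, water-permeability and gating calls.  ``run_qpcr``
chains efficiency estimation, Cq calling, noRT exclusion, geNorm
reference selection, CNRQ computation and the robust group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassLabel, classify_by_residues
from .errors import AnalysisError
from .extraction import (ResidueExtraction, alignment_score, extract_for_query,
                         scan_npa)
from .qpcr import (CnrqTable, StabilityRanking, brown_forsythe, compute_cnrq,
                   compute_cq, estimate_efficiency, filter_noRT,
                   genorm_stability, scheffe_posthoc)
from .refdata import (ReferenceAnnotation, SignatureRuleSet,
                      load_shipped_annotations, load_shipped_rules)
from .seqio import ProteinRecord
from .substrates import (GatingProfile, PermeabilityCall, SubstrateCall,
                         Verdict, consensus_prediction, gating_profile,
                         match_sdp, match_ssss, permeability_call)
from .synth import WellRecord
from .topology import (NpaTopologyReport, TopologyMap, hydropathy_profile,
                       locate_npa_in_topology, predict_tm_helices)


@dataclass(frozen=True)
class AnnotationResult:
    query_id: str
    topology: TopologyMap | None
    npa_hits: tuple[tuple[int, str], ...]
    npa_report: NpaTopologyReport | None
    extraction: ResidueExtraction
    class_label: ClassLabel
    substrate_call: SubstrateCall
    permeability: PermeabilityCall
    gating: GatingProfile
    warnings: tuple[str, ...] = ()


def choose_reference(query: ProteinRecord,
                     annotations: dict[str, ReferenceAnnotation],
                     class_hint: str | None = None) -> ReferenceAnnotation:
    """Pick the class reference, by hint or by best global-alignment score."""
    if class_hint:
        return annotations[class_hint]
    scored = sorted(
        annotations.values(),
        key=lambda a: -alignment_score(query, a.reference))
    return scored[0]


def annotate_record(query: ProteinRecord,
                    annotations: dict[str, ReferenceAnnotation],
                    rulesets: dict[tuple[str, str], SignatureRuleSet],
                    policy: str = "abstain-on-undefined",
                    class_hint: str | None = None) -> AnnotationResult:
    warnings: list[str] = []
    npa_hits = tuple(scan_npa(query))
    topology = npa_report = None
    try:
        prof = hydropathy_profile(query)
        topology = predict_tm_helices(prof, query.id)
        if topology.n_helices != 6:
            warnings.append(f"{topology.n_helices} helices predicted "
                            "(expected 6); loop labels are numeric")
        npa_report = locate_npa_in_topology(topology, list(npa_hits))
        warnings.extend(npa_report.warnings)
    except AnalysisError as exc:
        warnings.append(f"topology skipped: {exc}")

    annotation = choose_reference(query, annotations, class_hint)
    ext = extract_for_query(query, annotation)
    label = classify_by_residues(ext)
    verdicts: list[Verdict] = []
    for rs in rulesets.values():
        match = match_ssss if rs.kind == "ssss" else match_sdp
        verdicts.extend(match(ext, rs).values())
    consensus = consensus_prediction(verdicts, policy=policy)
    call = SubstrateCall(query_id=query.id, verdicts=tuple(verdicts),
                         consensus=consensus, policy=policy)
    return AnnotationResult(
        query_id=query.id, topology=topology, npa_hits=npa_hits,
        npa_report=npa_report, extraction=ext, class_label=label,
        substrate_call=call, permeability=permeability_call(ext),
        gating=gating_profile(ext), warnings=tuple(warnings))


def annotate_records(records: list[ProteinRecord],
                     annotations: dict[str, ReferenceAnnotation] | None = None,
                     rulesets: dict[tuple[str, str], SignatureRuleSet] | None = None,
                     policy: str = "abstain-on-undefined") -> list[AnnotationResult]:
    if not records:
        raise AnalysisError("no input sequences")
    annotations = annotations or load_shipped_annotations()
    rulesets = rulesets or load_shipped_rules()
    return [annotate_record(r, annotations, rulesets, policy) for r in records]


# ---------------------------------------------------------------------------
# report frames
# ---------------------------------------------------------------------------

def extraction_frame(results: list[AnnotationResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for name, (ref_c, q_c, residue) in res.extraction.positions.items():
            rows.append((res.query_id, name, ref_c,
                         q_c if q_c is not None else "gap", residue))
    return pd.DataFrame(rows, columns=["query", "position", "ref_coord",
                                       "query_coord", "residue"])


def substrate_frame(results: list[AnnotationResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for v in res.substrate_call.verdicts:
            rows.append((res.query_id, v.source, v.kind, v.substrate,
                         v.verdict, ";".join(v.mismatches),
                         v.substrate in res.substrate_call.consensus))
    return pd.DataFrame(rows, columns=["query", "source", "kind", "substrate",
                                       "verdict", "mismatch_positions",
                                       "in_consensus"])


def topology_frame(results: list[AnnotationResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        if res.topology is None:
            continue
        for k, ((a, b), mh) in enumerate(zip(res.topology.helices,
                                             res.topology.mean_hydropathy), 1):
            rows.append((res.query_id, k, a, b, round(mh, 3)))
    return pd.DataFrame(rows, columns=["query", "helix", "start", "end",
                                       "mean_hydropathy"])


def summary_frame(results: list[AnnotationResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        rows.append((
            res.query_id,
            res.class_label.class_name, res.class_label.subtype,
            res.topology.n_helices if res.topology else 0,
            len(res.npa_hits),
            res.extraction.arr, res.extraction.froger,
            res.extraction.loopD_residue,
            res.permeability.verdict,
            "yes" if res.gating.all_present else "no",
            ",".join(sorted(res.substrate_call.consensus)) or "-",
            "; ".join(res.warnings) or "-",
        ))
    return pd.DataFrame(rows, columns=[
        "query", "class", "subtype", "n_helices", "n_npa", "arr", "froger",
        "loopD", "permeability", "gating_complete", "consensus", "warnings"])


# ---------------------------------------------------------------------------
# qPCR flow
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrRunResult:
    efficiencies: dict[str, float]
    efficiency_detail: pd.DataFrame
    cq_table: pd.DataFrame                   # post noRT filter, long form
    nort_log: pd.DataFrame
    stability: StabilityRanking
    cnrq: CnrqTable
    stats: pd.DataFrame                      # per target, across tissue groups


def run_qpcr(wells: list[WellRecord], design: pd.DataFrame,
             reference_candidates: list[str],
             min_delta: float = 5.0, alpha: float = 0.05) -> QpcrRunResult:
    """The full expression-profiling computation on one plate.

    ``design`` maps samples to tissue groups (columns: sample, tissue).
    Reference genes are selected from ``reference_candidates`` by geNorm
    (the final stable pair); statistics compare log10 CNRQ across
    tissue groups per target with Brown-Forsythe + Scheffe.
    """
    tissue_of = dict(zip(design["sample"], design["tissue"]))

    by_target: dict[str, list[WellRecord]] = {}
    for w in wells:
        by_target.setdefault(w.target, []).append(w)

    eff_detail_rows = []
    efficiencies: dict[str, float] = {}
    for target, ws in by_target.items():
        est = estimate_efficiency(ws)
        efficiencies[target] = est.efficiency
        for we in est.wells:
            eff_detail_rows.append((target, we.sample, we.efficiency,
                                    we.r2, we.flagged, we.reason or ""))
    eff_detail = pd.DataFrame(eff_detail_rows, columns=[
        "target", "sample", "efficiency", "r2", "flagged", "reason"])

    # Cq per well, then the noRT exclusion rule
    cq: dict[tuple[str, str, str], float | None] = {}
    for w in wells:
        cq[(w.sample, w.target, w.well_type)] = compute_cq(w)
    nort_rows, kept_rows = [], []
    for (sample, target, wtype), value in cq.items():
        if wtype != "sample":
            continue
        decision = filter_noRT(value, cq.get((sample, target, "noRT")),
                               min_delta=min_delta)
        nort_rows.append((sample, target, value,
                          cq.get((sample, target, "noRT")),
                          decision.delta, decision.keep, decision.reason))
        if decision.keep:
            kept_rows.append((sample, target, value))
    nort_log = pd.DataFrame(nort_rows, columns=[
        "sample", "target", "sample_cq", "noRT_cq", "delta", "keep", "reason"])
    cq_table = pd.DataFrame(kept_rows, columns=["sample", "target", "cq"])

    candidates = [c for c in reference_candidates if c in by_target]
    wide = cq_table.pivot_table(index="sample", columns="target", values="cq")
    stability = genorm_stability(wide[candidates], efficiencies)
    references = stability.selected_pair

    cnrq = compute_cnrq(cq_table, efficiencies, references)

    stats_rows = []
    tab = cnrq.table.copy()
    tab["tissue"] = tab["sample"].map(tissue_of)
    for target, grp in tab.groupby("target"):
        if target in references:
            continue
        groups = [np.log10(g["cnrq"].dropna().to_numpy())
                  for _, g in grp.groupby("tissue")]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            continue
        bf = brown_forsythe(groups)
        n_sig = sum(c.significant for c in scheffe_posthoc(groups, alpha=alpha))
        stats_rows.append((target, bf.f_star, bf.df1, bf.df2, bf.p_value,
                           bf.p_value < alpha, n_sig))
    stats = pd.DataFrame(stats_rows, columns=[
        "target", "f_star", "df1", "df2", "p_value", "significant",
        "n_significant_pairs"])
    return QpcrRunResult(efficiencies=efficiencies, efficiency_detail=eff_detail,
                         cq_table=cq_table, nort_log=nort_log,
                         stability=stability, cnrq=cnrq, stats=stats)
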