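"""Substrate-specificity calls from SSSS and SDP signature matching.

A substrate *matches* a source's rule when every defined position
carries the expected residue; exactly one mismatching position is
reported as a *near-miss* (never counted as a match); a gap at any rule
position makes the comparison *not-comparable*; a (class, substrate)
pair without a rule is *not-defined*.  The consensus combines the
per-source verdicts; the default policy requires a defined match from
every SSSS source while SDP sources abstain where they define no rule
(the published SDP lists are additional constraints, not full
coverage).  ``strict-intersection`` additionally turns SDP abstentions
into vetoes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import AnalysisError
from .extraction import GAP, ResidueExtraction
from .refdata import SUBSTRATES, SdpRule, SignatureRuleSet, SsssRule

VERDICTS = ("match", "near-miss", "mismatch", "not-defined", "not-comparable")
POLICIES = ("strict-intersection", "abstain-on-undefined")
WILDCARD = "X"


@dataclass(frozen=True)
class Verdict:
    substrate: str
    source: str
    kind: str                       # ssss | sdp
    verdict: str
    mismatches: tuple[str, ...] = ()  # position names / coordinates

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise AnalysisError(f"unknown verdict {self.verdict!r}")


@dataclass(frozen=True)
class SubstrateCall:
    query_id: str
    verdicts: tuple[Verdict, ...]
    consensus: frozenset[str]
    policy: str

    def verdict(self, source: str, kind: str, substrate: str) -> Verdict:
        for v in self.verdicts:
            if (v.source, v.kind, v.substrate) == (source, kind, substrate):
                return v
        raise KeyError((source, kind, substrate))

    def matches(self, source: str, kind: str) -> frozenset[str]:
        return frozenset(v.substrate for v in self.verdicts
                         if (v.source, v.kind) == (source, kind)
                         and v.verdict == "match")


def _classify_mismatches(mismatch_coords: set, gapped: bool) -> tuple[str, tuple]:
    if gapped:
        return "not-comparable", tuple(sorted(map(str, mismatch_coords)))
    if not mismatch_coords:
        return "match", ()
    if len(mismatch_coords) == 1:
        return "near-miss", tuple(sorted(map(str, mismatch_coords)))
    return "mismatch", tuple(sorted(map(str, mismatch_coords)))


def match_ssss(ext: ResidueExtraction, rules: SignatureRuleSet,
               source: str | None = None) -> dict[str, Verdict]:
    """Per-substrate SSSS verdicts for one source.

    Mismatching positions are de-duplicated by reference coordinate, so
    an Ar/R position inside the loop-E window counts once.
    """
    if rules.kind != "ssss":
        raise AnalysisError("match_ssss requires an SSSS rule set")
    source = source or rules.source
    out: dict[str, Verdict] = {}
    for substrate in SUBSTRATES:
        rule = rules.rule_for(ext.class_hint, substrate)
        if rule is None:
            out[substrate] = Verdict(substrate, source, "ssss", "not-defined")
            continue
        assert isinstance(rule, SsssRule)
        mismatch_coords: set[int] = set()
        gapped = False
        for name, expected in rule.positions():
            if expected == WILDCARD:
                continue
            coord, _qc, observed = ext.positions[name]
            if observed == GAP:
                gapped = True
                mismatch_coords.add(coord)
            elif observed != expected:
                mismatch_coords.add(coord)
        verdict, mism = _classify_mismatches(mismatch_coords, gapped)
        out[substrate] = Verdict(substrate, source, "ssss", verdict, mism)
    return out


def match_sdp(ext: ResidueExtraction, rules: SignatureRuleSet,
              source: str | None = None) -> dict[str, Verdict]:
    """Per-substrate SDP verdicts for one source."""
    if rules.kind != "sdp":
        raise AnalysisError("match_sdp requires an SDP rule set")
    source = source or rules.source
    out: dict[str, Verdict] = {}
    for substrate in SUBSTRATES:
        rule = rules.rule_for(ext.class_hint, substrate)
        if rule is None:
            out[substrate] = Verdict(substrate, source, "sdp", "not-defined")
            continue
        assert isinstance(rule, SdpRule)
        mismatch_coords: set[int] = set()
        gapped = False
        observed = dict(ext.sdp_vector(substrate))
        for coord, allowed in rule.residues.items():
            res = observed.get(coord, GAP)
            if res == GAP:
                gapped = True
                mismatch_coords.add(coord)
            elif res not in allowed:
                mismatch_coords.add(coord)
        verdict, mism = _classify_mismatches(mismatch_coords, gapped)
        out[substrate] = Verdict(substrate, source, "sdp", verdict, mism)
    return out


def consensus_prediction(verdicts: list[Verdict],
                         policy: str = "abstain-on-undefined") -> frozenset[str]:
    """Combine per-source verdicts into a consensus substrate set.

    ``abstain-on-undefined`` (default): a substrate is predicted iff
    every SSSS source defines a rule and calls a match, and every SDP
    source that defines a rule calls a match (an SDP source with no rule
    abstains).  ``strict-intersection``: every source, SSSS or SDP, must
    define a rule and call a match.
    """
    if policy not in POLICIES:
        raise AnalysisError(f"unknown consensus policy {policy!r}")
    by_substrate: dict[str, list[Verdict]] = {}
    for v in verdicts:
        by_substrate.setdefault(v.substrate, []).append(v)
    consensus = set()
    for substrate, vs in by_substrate.items():
        votes = []
        for v in vs:
            if v.verdict == "not-defined":
                if policy == "strict-intersection" or v.kind == "ssss":
                    votes.append(False)
                # else: SDP source abstains
            else:
                votes.append(v.verdict == "match")
        if votes and all(votes):
            consensus.add(substrate)
    return frozenset(consensus)


# ---------------------------------------------------------------------------
# Permeability and gating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermeabilityCall:
    verdict: str                    # low-PIP1-like | high-PIP2-like | undetermined
    pair: tuple[str, str] | None


def permeability_call(ext: ResidueExtraction) -> PermeabilityCall:
    """Water-permeability indication from the (TM2, loop E) residue pair.

    (A, I) marks the lower-permeability PIP1 pattern; (I/V, V) the
    higher-permeability PIP2 pattern; anything else is undetermined.
    """
    pair = ext.permeability_pair
    if pair is None:
        return PermeabilityCall("undetermined", None)
    tm2, loope = pair
    if (tm2, loope) == ("A", "I"):
        return PermeabilityCall("low-PIP1-like", pair)
    if tm2 in ("I", "V") and loope == "V":
        return PermeabilityCall("high-PIP2-like", pair)
    return PermeabilityCall("undetermined", pair)


@dataclass(frozen=True)
class GatingProfile:
    sites: dict[str, tuple[str, str]]  # site -> (status, observed residue)

    def status(self, site: str) -> str:
        return self.sites[site][0]

    @property
    def all_present(self) -> bool:
        return all(s == "present" for s, _ in self.sites.values())


def gating_profile(ext: ResidueExtraction) -> GatingProfile:
    """Presence/absence of the conserved gating and modification sites.

    A site is *present* when the query carries the conserved residue,
    i.e. the residue of the annotated reference at that coordinate
    (Ser/Thr phosphosites, the loop-D His protonation site, the
    methylation Lys/Glu and the blocking Leu — Ile in TIPs).
    """
    sites = {}
    for site, observed in ext.gating_residues.items():
        coord = ext.positions[f"site.{site}"][0]
        expected = ext.annotation.residue_at(coord)
        if observed == GAP:
            status = "gap"
        elif observed == expected:
            status = "present"
        else:
            status = "absent"
        sites[site] = (status, observed)
    return GatingProfile(sites=sites)
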