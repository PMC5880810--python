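"""Reference annotations and signature rule tables.

A :class:`ReferenceAnnotation` pins every named signature position of an
aquaporin class (NPA loop windows, Ar/R selectivity filter, Froger P1-P5,
gating and permeability sites, SDP sets) to 1-based coordinates on a
single annotated reference sequence.  A :class:`SignatureRuleSet` holds
the expected residues per (class, substrate) for one published source,
either at the SSSS positions (loop windows + Ar/R + Froger) or at the
SDP positions.

Both are plain-text INI configs shipped under ``aquasig/data/`` and
user-replaceable; all invariants are validated at load time.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ValidationError
from .seqio import ProteinRecord

ARR_NAMES = ("H2", "H5", "LE1", "LE2")
FROGER_NAMES = ("P1", "P2", "P3", "P4", "P5")
SUBSTRATES = ("h2o2", "urea", "boron", "co2", "ammonia")
SUBSTRATE_LABELS = {
    "h2o2": "H2O2",
    "urea": "urea",
    "boron": "boric acid/boron",
    "co2": "CO2",
    "ammonia": "ammonia",
}
CLASSES = ("PIP", "TIP")

# site keys: value True means the site is mandatory for the class config
PIP_SITES = ("loopB_Ser", "cterm_Ser", "loopD_His", "loopD_L",
             "methylation_K", "methylation_E")
TIP_SITES = ("loopB_phospho", "loopD_L")


@dataclass(frozen=True)
class ReferenceAnnotation:
    """Named signature positions on an annotated reference sequence."""

    reference: ProteinRecord
    class_label: str                      # "PIP" or "TIP"
    npa_loopB: tuple[int, int]            # (start, length), 1-based inclusive
    npa_loopE: tuple[int, int]
    arr: dict[str, int]                   # H2, H5, LE1, LE2 -> coordinate
    froger: dict[str, int]                # P1..P5 -> coordinate
    sites: dict[str, int]                 # gating / conserved sites
    sdp: dict[str, tuple[int, ...]]       # substrate -> coordinates
    permeability: tuple[int, int] | None  # (TM2 pos, loop E pos), PIP only

    def __post_init__(self) -> None:
        n = len(self.reference.seq)
        if self.class_label not in CLASSES:
            raise ValidationError(f"unknown class {self.class_label!r}")
        if len(self.arr) != 4 or tuple(self.arr) != ARR_NAMES:
            raise ValidationError("arr block must define exactly H2, H5, LE1, LE2")
        if len(self.froger) != 5 or tuple(self.froger) != FROGER_NAMES:
            raise ValidationError("froger block must define exactly P1..P5")
        for name, coord in self.iter_named_positions():
            if not (1 <= coord <= n):
                raise ValidationError(
                    f"position {name} = {coord} outside reference (length {n})")
        names = [name for name, _ in self.iter_named_positions()]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate named positions in annotation")

    # -- coordinate helpers -------------------------------------------------

    def window_coords(self, loop: str) -> tuple[int, ...]:
        start, length = self.npa_loopB if loop == "B" else self.npa_loopE
        return tuple(range(start, start + length))

    def iter_named_positions(self):
        """Yield every (name, 1-based coordinate) of the annotation."""
        for i, c in enumerate(self.window_coords("B"), 1):
            yield f"loopB[{i}]", c
        for i, c in enumerate(self.window_coords("E"), 1):
            yield f"loopE[{i}]", c
        for k, c in self.arr.items():
            yield f"arr.{k}", c
        for k, c in self.froger.items():
            yield f"froger.{k}", c
        for k, c in self.sites.items():
            yield f"site.{k}", c
        if self.permeability is not None:
            yield "perm.TM2", self.permeability[0]
            yield "perm.loopE", self.permeability[1]
        for sub, coords in self.sdp.items():
            for c in coords:
                yield f"sdp.{sub}.{c}", c

    def residue_at(self, coord: int) -> str:
        return self.reference.seq[coord - 1]

    def arr_residues(self) -> str:
        return "".join(self.residue_at(c) for c in self.arr.values())

    def froger_residues(self) -> str:
        return "".join(self.residue_at(c) for c in self.froger.values())


def _get(cfg: configparser.ConfigParser, section: str, option: str,
         path) -> str:
    try:
        return cfg.get(section, option)
    except (configparser.NoSectionError, configparser.NoOptionError) as exc:
        raise ValidationError(f"{path}: missing [{section}] {option}") from exc


def load_reference_annotation(path: str | Path) -> ReferenceAnnotation:
    """Load a reference annotation config (1-based inclusive coordinates)."""
    path = Path(path)
    cfg = configparser.ConfigParser(inline_comment_prefixes=("#",))
    if not cfg.read(path):
        raise ValidationError(f"{path}: cannot read annotation config")
    for block in ("reference", "npa", "arr", "froger"):
        if not cfg.has_section(block):
            raise ValidationError(f"{path}: missing mandatory block [{block}]")

    ref = ProteinRecord(
        _get(cfg, "reference", "id", path),
        "".join(_get(cfg, "reference", "sequence", path).split()),
    )
    class_label = _get(cfg, "reference", "class", path).strip().upper()

    def window(option: str) -> tuple[int, int]:
        parts = _get(cfg, "npa", option, path).split()
        if len(parts) != 2:
            raise ValidationError(f"{path}: [npa] {option} must be 'start length'")
        return int(parts[0]), int(parts[1])

    arr = {k: int(_get(cfg, "arr", k, path)) for k in ARR_NAMES}
    if set(cfg.options("arr")) != {k.lower() for k in ARR_NAMES}:
        raise ValidationError(f"{path}: [arr] must define exactly {ARR_NAMES}")
    if not cfg.has_section("froger") or len(cfg.options("froger")) != 5:
        raise ValidationError(f"{path}: [froger] must define exactly 5 positions")
    froger = {k: int(_get(cfg, "froger", k, path)) for k in FROGER_NAMES}

    sites = {}
    if cfg.has_section("sites"):
        wanted = PIP_SITES if class_label == "PIP" else TIP_SITES
        lower = {k.lower(): k for k in wanted}
        for opt in cfg.options("sites"):
            if opt not in lower:
                raise ValidationError(f"{path}: unknown site {opt!r} for class "
                                      f"{class_label}")
            sites[lower[opt]] = int(cfg.get("sites", opt))

    sdp: dict[str, tuple[int, ...]] = {}
    if cfg.has_section("sdp"):
        for opt in cfg.options("sdp"):
            if opt not in SUBSTRATES:
                raise ValidationError(f"{path}: unknown SDP substrate {opt!r}")
            sdp[opt] = tuple(int(x) for x in cfg.get("sdp", opt).split())

    permeability = None
    if cfg.has_section("permeability"):
        permeability = (int(_get(cfg, "permeability", "TM2", path)),
                        int(_get(cfg, "permeability", "loopE", path)))

    try:
        return ReferenceAnnotation(
            reference=ref, class_label=class_label,
            npa_loopB=window("loopB_window"), npa_loopE=window("loopE_window"),
            arr=arr, froger=froger, sites=sites, sdp=sdp,
            permeability=permeability,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Signature rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SsssRule:
    """Expected residues of one substrate-specific signature sequence.

    Strings over the amino-acid alphabet plus ``X`` (position not
    constrained by the source).
    """

    loopB: str
    loopE: str
    arr: str
    froger: str

    def positions(self):
        yield from ((f"loopB[{i}]", r) for i, r in enumerate(self.loopB, 1))
        yield from ((f"loopE[{i}]", r) for i, r in enumerate(self.loopE, 1))
        yield from ((f"arr.{n}", r) for n, r in zip(ARR_NAMES, self.arr))
        yield from ((f"froger.{n}", r) for n, r in zip(FROGER_NAMES, self.froger))


@dataclass(frozen=True)
class SdpRule:
    """Expected residues at specificity-determining positions.

    ``residues`` maps reference coordinate -> set of allowed residues
    (a source may list alternatives, written ``A/L`` in the config).
    """

    residues: dict[int, frozenset[str]]


@dataclass(frozen=True)
class SignatureRuleSet:
    """All rules of one source ('hove' or 'azad'), one kind ('ssss'|'sdp')."""

    source: str
    kind: str
    entries: dict[tuple[str, str], SsssRule | SdpRule] = field(default_factory=dict)

    def rule_for(self, class_label: str, substrate: str):
        """Return the rule or None when the source defines none ('not defined')."""
        return self.entries.get((class_label, substrate))

    @property
    def substrates(self) -> tuple[str, ...]:
        return tuple(sorted({s for _, s in self.entries}))


def _parse_residue_token(token: str) -> frozenset[str]:
    alts = frozenset(token.split("/"))
    if not alts or not all(len(a) == 1 and (a.isalpha()) for a in alts):
        raise ValidationError(f"bad residue token {token!r}")
    return alts


def load_rules(path: str | Path,
               annotation_by_class: dict[str, ReferenceAnnotation] | None = None,
               ) -> SignatureRuleSet:
    """Load a signature rule config (one source, SSSS or SDP kind).

    When ``annotation_by_class`` is given, SDP coordinates and SSSS window
    lengths are validated against the corresponding annotation, and SSSS
    entries are checked for internal consistency where the Ar/R positions
    fall inside the loop E window.
    """
    path = Path(path)
    cfg = configparser.ConfigParser(inline_comment_prefixes=("#",))
    if not cfg.read(path):
        raise ValidationError(f"{path}: cannot read rule config")
    source = _get(cfg, "meta", "source", path).strip()
    kind = _get(cfg, "meta", "kind", path).strip()
    if kind not in ("ssss", "sdp"):
        raise ValidationError(f"{path}: kind must be 'ssss' or 'sdp'")

    entries: dict[tuple[str, str], SsssRule | SdpRule] = {}
    for section in cfg.sections():
        if section == "meta":
            continue
        parts = section.split()
        if len(parts) != 2:
            raise ValidationError(f"{path}: section [{section}] must be "
                                  "'<class> <substrate>'")
        class_label, substrate = parts[0].upper(), parts[1].lower()
        if class_label not in CLASSES:
            raise ValidationError(f"{path}: unknown class token {parts[0]!r}")
        if substrate not in SUBSTRATES:
            raise ValidationError(f"{path}: unknown substrate token {parts[1]!r}")
        key = (class_label, substrate)
        if key in entries:
            raise ValidationError(f"{path}: duplicate entry for "
                                  f"({source}, {class_label}, {substrate})")
        if kind == "ssss":
            rule = SsssRule(
                loopB=_get(cfg, section, "loopB", path).strip().upper(),
                loopE=_get(cfg, section, "loopE", path).strip().upper(),
                arr=_get(cfg, section, "arr", path).strip().upper(),
                froger=_get(cfg, section, "froger", path).strip().upper(),
            )
            if len(rule.arr) != 4 or len(rule.froger) != 5:
                raise ValidationError(f"{path}: [{section}] arr/froger lengths "
                                      "must be 4 and 5")
        else:
            residues = {}
            for token in _get(cfg, section, "residues", path).split():
                pos_s, _, res_s = token.partition(":")
                try:
                    pos = int(pos_s)
                except ValueError as exc:
                    raise ValidationError(f"{path}: bad SDP token {token!r}") from exc
                residues[pos] = _parse_residue_token(res_s)
            rule = SdpRule(residues=residues)
        entries[key] = rule

    ruleset = SignatureRuleSet(source=source, kind=kind, entries=entries)
    if annotation_by_class:
        _validate_rules_against_annotation(ruleset, annotation_by_class, path)
    return ruleset


def _validate_rules_against_annotation(ruleset, annotation_by_class, path):
    for (class_label, substrate), rule in ruleset.entries.items():
        ann = annotation_by_class.get(class_label)
        if ann is None:
            continue
        if isinstance(rule, SsssRule):
            for loop, s in (("B", rule.loopB), ("E", rule.loopE)):
                if len(s) != len(ann.window_coords(loop)):
                    raise ValidationError(
                        f"{path}: [{class_label} {substrate}] loop{loop} length "
                        f"{len(s)} != annotation window {len(ann.window_coords(loop))}")
            # Ar/R positions inside loop E window must agree with the window string
            ecoords = ann.window_coords("E")
            for arr_name, arr_res in zip(ARR_NAMES, rule.arr):
                coord = ann.arr[arr_name]
                if coord in ecoords:
                    w = rule.loopE[ecoords.index(coord)]
                    if "X" not in (w, arr_res) and w != arr_res:
                        raise ValidationError(
                            f"{path}: [{class_label} {substrate}] arr {arr_name} "
                            f"({arr_res}) conflicts with loopE window ({w})")
        else:
            known = set(ann.sdp.get(substrate, ()))
            for pos in rule.residues:
                if pos not in known:
                    raise ValidationError(
                        f"{path}: [{class_label} {substrate}] SDP position {pos} "
                        "not in the annotation's SDP set")


# ---------------------------------------------------------------------------
# Shipped data
# ---------------------------------------------------------------------------

def data_path(name: str) -> Path:
    """Path of a shipped data file (reference/rule configs)."""
    return Path(resources.files("aquasig") / "data" / name)


def load_shipped_annotations() -> dict[str, ReferenceAnnotation]:
    return {
        "PIP": load_reference_annotation(data_path("pip_reference.cfg")),
        "TIP": load_reference_annotation(data_path("tip_reference.cfg")),
    }


def load_shipped_rules() -> dict[tuple[str, str], SignatureRuleSet]:
    """Shipped rule sets keyed by (source, kind)."""
    ann = load_shipped_annotations()
    out = {}
    for name in ("ssss_hove.cfg", "ssss_azad.cfg", "sdp_hove.cfg"):
        rs = load_rules(data_path(name), ann)
        out[(rs.source, rs.kind)] = rs
    return out
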