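"""Synthetic fixtures: motif-bearing aquaporin sequences and qPCR plates.

Real aquaporin sequences live in GenBank; to keep the package fully
self-contained the generators here build *synthetic* stand-ins: each
group template embeds the group's published signature residues (NPA
loop windows, Ar/R filter, Froger P1-P5, SDPs, gating and permeability
sites) at the annotated reference coordinates, inside a six-helix
hydrophobic scaffold with hydrophilic linkers.  A documented hook
(:func:`make_group_sequence` accepts any template) lets users substitute
real translations when available.

The qPCR simulator emulates the expression study design: seven tissue
classes (young/mature leaf, petiole, four fruit stages) in three
biological replicates, eight aquaporin target groups with the published
amplification efficiencies, two stable reference genes (E = 1.911) plus
extra candidate references, noRT controls and multiplicative noise.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .seqio import ProteinRecord

TM_ALPHABET = "ILVF"          # strongly hydrophobic fill
LOOP_ALPHABET = "GSTNQKDP"    # hydrophilic/neutral fill
LOOPD_ALPHABET = "NQKD"       # strongly polar, keeps TM4/TM5 separated


# ---------------------------------------------------------------------------
# Scaffold layouts (1-based inclusive segment coordinates)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaffoldLayout:
    length: int
    segments: tuple[tuple[str, int, int], ...]  # (kind, start, end)

    def kind_at(self, coord: int) -> str:
        for kind, a, b in self.segments:
            if a <= coord <= b:
                return kind
        raise ValidationError(f"coordinate {coord} outside layout")

    def tm_segments(self) -> list[tuple[int, int]]:
        return [(a, b) for kind, a, b in self.segments if kind == "tm"]


PIP_LAYOUT = ScaffoldLayout(
    length=289,
    segments=(
        ("term", 1, 33),
        ("tm", 34, 57),
        ("loop", 58, 83),
        ("tm", 84, 107),
        ("loop", 108, 131),
        ("tm", 132, 155),
        ("loop", 156, 177),
        ("tm", 178, 201),
        ("loopD", 202, 211),
        ("tm", 212, 235),
        ("loop", 236, 257),
        ("tm", 258, 285),
        ("term", 286, 289),
    ),
)

TIP_LAYOUT = ScaffoldLayout(
    length=252,
    segments=(
        ("term", 1, 12),
        ("tm", 13, 36),
        ("loop", 37, 50),
        ("tm", 51, 74),
        ("loop", 75, 99),
        ("tm", 100, 123),
        ("loop", 124, 139),
        ("tm", 140, 163),
        ("loopD", 164, 175),
        ("tm", 176, 197),
        ("loop", 198, 217),
        ("tm", 218, 246),
        ("term", 247, 252),
    ),
)


# ---------------------------------------------------------------------------
# Group templates (signature residues per named coordinate)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupTemplate:
    """Signature residues of one expression group on its class scaffold."""

    group_id: str
    class_label: str                  # PIP | TIP (annotation reference class)
    residues: dict[int, str]          # 1-based coordinate -> residue
    layout: ScaffoldLayout = field(repr=False)

    @property
    def subtype(self) -> str:
        """Scaffold lineage: PIP1, PIP2 or TIP (controls the base linkers)."""
        if self.group_id.startswith("FaPIP2"):
            return "PIP2"
        if self.group_id.startswith("FaPIP"):
            return "PIP1"
        return "TIP"


def _window_residues(start: int, window: str) -> dict[int, str]:
    return {start + i: r for i, r in enumerate(window)}


def _pip_residues(loopB: str, loopE: str, froger: str,
                  perm: tuple[str, str], sdp_overrides: dict[int, str]
                  ) -> dict[int, str]:
    base = {}
    base.update(_window_residues(112, loopB))
    base.update(_window_residues(236, loopE))
    base.update({98: "F", 216: "H"})                      # Ar/R H2, H5
    base.update({170: froger[0], 222: froger[1], 230: froger[2],
                 263: froger[3], 269: froger[4]})          # Froger P1-P5
    base.update({3: "K", 6: "E", 204: "H", 208: "L", 287: "S"})  # gating
    base.update({103: perm[0], 249: perm[1]})              # permeability
    # SDP residues of the FaPIP1;1 baseline (Table-3-style listing)
    base.update({108: "T", 111: "I", 115: "H", 118: "P", 186: "E",
                 226: "L", 229: "L", 231: "T", 233: "P",           # boric acid
                 136: "V", 139: "I", 143: "T", 146: "A", 214: "I",
                 254: "K", 257: "W", 259: "D", 261: "W",           # CO2
                 149: "G", 153: "V", 156: "F", 220: "I", 260: "H",
                 265: "V", 267: "P",                               # H2O2
                 122: "F", 125: "F", 193: "L", 238: "G", 240: "N"})  # urea
    for pos, res in sdp_overrides.items():
        base[pos] = res
    return base


def _tip_residues(loopB: str, loopE: str, froger: str,
                  sdp_overrides: dict[int, str]) -> dict[int, str]:
    base = {}
    base.update(_window_residues(82, loopB))
    base.update(_window_residues(198, loopE))
    base.update({60: "H", 185: "I"})                       # Ar/R H2, H5
    base.update({211: froger[0], 214: froger[1], 216: froger[2],
                 222: froger[3], 230: froger[4]})
    base.update({97: "T", 168: "I"})                       # phosphosite, loop-D Ile
    # SDP residues of the FaTIP(a) baseline
    base.update({116: "A", 119: "A", 123: "L", 126: "V", 182: "I",
                 219: "H", 224: "L", 226: "P",                      # H2O2
                 85: "H", 88: "P", 92: "F", 95: "L", 158: "L",
                 195: "P", 200: "S", 202: "N"})                     # urea
    for pos, res in sdp_overrides.items():
        base[pos] = res
    return base


def _check_window_consistency(residues: dict[int, str], start: int,
                              window: str, group: str) -> None:
    for i, r in enumerate(window):
        if residues[start + i] != r:
            raise ValidationError(
                f"{group}: residue at {start + i} ({residues[start + i]}) "
                f"conflicts with window letter {r}")


def _make_templates() -> dict[str, GroupTemplate]:
    pip_b = "SGGHINPAVT"
    pip_e = "GTGINPARSLG"
    pip_e_22 = "GTGINPARSFG"         # FaPIP2;2: one loop-E letter differs
    specs = {
        "FaPIP1;1": ("PIP", pip_b, pip_e, "ESAFW", ("A", "I"), {}),
        "FaPIP1;2": ("PIP", pip_b, pip_e, "ESAFW", ("A", "I"),
                     {254: "E", 259: "H"}),
        "FaPIP1;3": ("PIP", pip_b, pip_e, "QSAFW", ("A", "I"),
                     {254: "A", 260: "Q"}),
        "FaPIP2;1(a)": ("PIP", pip_b, pip_e, "QSAFW", ("I", "V"),
                        {143: "S", 214: "V", 226: "M", 260: "Q"}),
        "FaPIP2;1(b)": ("PIP", pip_b, pip_e, "QSAFW", ("I", "V"),
                        {143: "S", 214: "V", 226: "M", 260: "Q"}),
        "FaPIP2;2": ("PIP", pip_b, pip_e_22, "QSAFW", ("V", "V"),
                     {143: "S", 214: "V", 226: "M", 254: "D", 265: "L"}),
        "FaTIP(a)": ("TIP", "SGGHVNPAVT", "GASMNPARAFG", "TAAYW", None, {}),
        "FaTIP(b)": ("TIP", "SGGHLNPAVT", "GGSMNPARSFG", "TSAYW", None,
                     {116: "S", 219: "N", 224: "V", 95: "A"}),
    }
    out = {}
    for gid, (cls, loopB, loopE, froger, perm, over) in specs.items():
        if cls == "PIP":
            residues = _pip_residues(loopB, loopE, froger, perm, over)
            layout = PIP_LAYOUT
            _check_window_consistency(residues, 112, loopB, gid)
            _check_window_consistency(residues, 236, loopE, gid)
        else:
            residues = _tip_residues(loopB, loopE, froger, over)
            layout = TIP_LAYOUT
            _check_window_consistency(residues, 82, loopB, gid)
            _check_window_consistency(residues, 198, loopE, gid)
        out[gid] = GroupTemplate(gid, cls, residues, layout)
    return out


GROUP_TEMPLATES: dict[str, GroupTemplate] = _make_templates()
GROUP_IDS: tuple[str, ...] = tuple(GROUP_TEMPLATES)

# class exemplars used for reference panels and the shipped references
CLASS_EXEMPLARS = {"PIP1": "FaPIP1;1", "PIP2": "FaPIP2;1(a)", "TIP": "FaTIP(a)"}


_BASE_SEED = {"PIP1": 101, "TIP": 202}
_SUBTYPE_SHIFT_SEED = {"PIP2": 303}
SUBTYPE_BASE_DIVERGENCE = 0.30    # PIP2 scaffold vs the PIP1 scaffold
DEFAULT_LINKER_DIVERGENCE = 0.08


def _segment_alphabet(kind: str) -> str:
    return {"tm": TM_ALPHABET, "loopD": LOOPD_ALPHABET}.get(kind, LOOP_ALPHABET)


def _base_chars(layout: ScaffoldLayout, subtype: str) -> list[str]:
    """Deterministic per-subtype scaffold fill shared by all its members.

    Members of one subtype are near-identical outside the signature
    positions (as real within-subtype homologs are), so coordinate
    transfer through the global alignment stays unambiguous.  The PIP2
    scaffold derives from the PIP1 scaffold by mutating a fixed fraction
    of sites, mirroring the genome-wide divergence that separates the
    subtypes phylogenetically beyond their few signature residues.
    """
    root = "PIP1" if subtype in ("PIP1", "PIP2") else "TIP"
    rng = np.random.default_rng(_BASE_SEED[root])
    chars = [_segment_alphabet(layout.kind_at(c))[
        rng.integers(len(_segment_alphabet(layout.kind_at(c))))]
        for c in range(1, layout.length + 1)]
    if subtype in _SUBTYPE_SHIFT_SEED:
        shift = np.random.default_rng(_SUBTYPE_SHIFT_SEED[subtype])
        for c in range(1, layout.length + 1):
            if shift.random() < SUBTYPE_BASE_DIVERGENCE:
                alphabet = _segment_alphabet(layout.kind_at(c))
                chars[c - 1] = alphabet[shift.integers(len(alphabet))]
    return chars


def make_group_sequence(template: GroupTemplate, seed: int,
                        record_id: str | None = None,
                        divergence: float = DEFAULT_LINKER_DIVERGENCE
                        ) -> ProteinRecord:
    """Build one synthetic sequence for a group template.

    Named signature positions carry exactly the template's residues.
    Linkers start from the deterministic class scaffold (hydrophobic
    fill in transmembrane segments, hydrophilic in loops) and mutate
    per-site with probability ``divergence`` within the segment's own
    alphabet, deterministically for a given seed — so two seeds give
    different linkers but identical signature residues.
    """
    layout = template.layout
    if not 0.0 <= divergence <= 0.3:
        raise ValidationError("divergence must lie in [0, 0.3]")
    for pos in template.residues:
        if not (1 <= pos <= layout.length):
            raise ValidationError(
                f"{template.group_id}: residue position {pos} outside scaffold")
    chars = _base_chars(layout, template.subtype)
    rng = np.random.default_rng(seed)
    for coord in range(1, layout.length + 1):
        if coord in template.residues:
            chars[coord - 1] = template.residues[coord]
        elif divergence > 0 and rng.random() < divergence:
            alphabet = _segment_alphabet(layout.kind_at(coord))
            chars[coord - 1] = alphabet[rng.integers(len(alphabet))]
    _suppress_spurious_npa(chars, template)
    return ProteinRecord(record_id or template.group_id, "".join(chars))


def _suppress_spurious_npa(chars: list[str], template: GroupTemplate) -> None:
    """Rewrite linker residues that happen to spell an extra NPA motif.

    The two genuine motifs live at fixed window coordinates; any other
    occurrence must involve at least one non-signature position, which
    is deterministically bumped to a letter breaking the motif.
    """
    genuine = {i + 1 for i, _ in enumerate(chars)
               if template.residues.get(i + 1) == "N"
               and template.residues.get(i + 2) == "P"
               and template.residues.get(i + 3) == "A"}
    for i in range(len(chars) - 2):
        start = i + 1
        if start in genuine:
            continue
        if chars[i] == "N" and chars[i + 1] == "P" and chars[i + 2] == "A":
            for off in range(3):
                if (start + off) not in template.residues:
                    chars[i + off] = {"N": "Q", "P": "G", "A": "V"}[chars[i + off]]
                    break


def make_group_fixtures(seed: int = 1) -> list[ProteinRecord]:
    """One synthetic sequence per expression group (deterministic)."""
    return [make_group_sequence(GROUP_TEMPLATES[g], seed + i)
            for i, g in enumerate(GROUP_IDS)]


def make_reference_panel(n_per_class: int, divergence: float, seed: int
                         ) -> list[tuple[ProteinRecord, str]]:
    """A labelled panel: mutated copies of each class exemplar.

    Non-signature sites mutate with per-site probability ``divergence``
    (within the segment's own alphabet, preserving hydropathy);
    signature sites are never touched, so the classes stay separable.
    """
    if n_per_class < 2:
        raise ValidationError("n_per_class must be >= 2")
    if not 0.0 <= divergence <= 0.3:
        raise ValidationError("divergence must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)
    panel = []
    for label, gid in CLASS_EXEMPLARS.items():
        template = GROUP_TEMPLATES[gid]
        for k in range(n_per_class):
            rec = make_group_sequence(template, seed=int(rng.integers(2**31)),
                                      record_id=f"{label}_panel{k + 1}",
                                      divergence=divergence)
            panel.append((rec, label))
    return panel


def reference_record(class_label: str) -> ProteinRecord:
    """The deterministic synthetic reference sequence for a class
    (the unmutated class scaffold carrying the exemplar's signature)."""
    gid = {"PIP": "FaPIP1;1", "TIP": "FaTIP(a)"}[class_label]
    rid = {"PIP": "PIP_ref_synthetic", "TIP": "TIP_ref_synthetic"}[class_label]
    return make_group_sequence(GROUP_TEMPLATES[gid], seed=0, record_id=rid,
                               divergence=0.0)


# ---------------------------------------------------------------------------
# qPCR plate simulation
# ---------------------------------------------------------------------------

TISSUES = ("Ly", "Lm", "P", "sGF", "lGF", "WF", "RF")

# published per-group amplification efficiencies
GROUP_EFFICIENCIES = {
    "FaPIP1;1": 1.895, "FaPIP1;2": 1.902, "FaPIP1;3": 1.881,
    "FaPIP2;1(a)": 1.786, "FaPIP2;1(b)": 1.902, "FaPIP2;2": 1.897,
    "FaTIP(a)": 2.081, "FaTIP(b)": 1.903,
}
REFERENCE_EFFICIENCY = 1.911


@dataclass(frozen=True)
class WellRecord:
    sample: str
    target: str
    well_type: str                    # sample | noRT | NTC
    fluorescence: tuple[float, ...]   # indexed by cycle 1..N

    def __post_init__(self) -> None:
        if len(self.fluorescence) < 15:
            raise ValidationError("fluorescence series must span >= 15 cycles")
        if any(f < 0 for f in self.fluorescence):
            raise ValidationError("fluorescence readings must be nonnegative")
        if self.well_type not in ("sample", "noRT", "NTC"):
            raise ValidationError(f"unknown well type {self.well_type!r}")


@dataclass(frozen=True)
class QpcrSimDesign:
    """Ground truth of a simulated plate."""

    targets: dict[str, float]                       # target -> efficiency E
    reference_targets: tuple[str, ...]
    samples: tuple[tuple[str, str], ...]            # (sample id, tissue)
    expression: dict[tuple[str, str], float]        # (tissue, target) -> level
    noise_sigma: float = 0.01                       # multiplicative, lognormal
    nort_offset: dict[str, float] | float = 8.0     # cycles; per-sample or scalar
    cycles: int = 40
    seed: int = 0
    baseline: float = 0.05
    plateau: float = 10.0
    ch_half: float = 24.0                           # midpoint cycle at level 1

    def __post_init__(self) -> None:
        for t, e in self.targets.items():
            if not 1.0 < e <= 2.2:
                raise ValidationError(f"efficiency of {t} outside (1, 2.2]")
        for key, x in self.expression.items():
            if x <= 0:
                raise ValidationError(f"nonpositive expression level for {key}")

    def offset_for(self, sample: str) -> float:
        if isinstance(self.nort_offset, dict):
            return self.nort_offset.get(sample, 8.0)
        return float(self.nort_offset)


def default_design(seed: int = 42, noise_sigma: float = 0.01,
                   n_replicates: int = 3) -> QpcrSimDesign:
    """The study-like default: 7 tissues x 3 replicates, 8 target groups,
    two stable reference genes and two unstable reference candidates."""
    targets = dict(GROUP_EFFICIENCIES)
    targets["clathrin"] = REFERENCE_EFFICIENCY
    targets["CHP3"] = REFERENCE_EFFICIENCY
    targets["EF1a"] = 1.93
    targets["GAPDH"] = 1.88
    samples = tuple((f"{t}_{r + 1}", t)
                    for t in TISSUES for r in range(n_replicates))
    # programmed tissue profiles: 2x and 4x steps around a base level,
    # qualitatively echoing leaf-specific / fruit-specific patterns
    profiles = {
        "FaPIP1;1": (2, 2, 2, 4, 4, 2, 1),
        "FaPIP1;2": (1, 1, 1, 1, 1, 1, 1),
        "FaPIP1;3": (4, 4, 0.5, 0.5, 0.5, 0.25, 0.25),
        "FaPIP2;1(a)": (1, 1, 1, 1, 2, 2, 4),
        "FaPIP2;1(b)": (4, 4, 4, 1, 1, 2, 2),
        "FaPIP2;2": (2, 2, 2, 4, 2, 1, 0.5),
        "FaTIP(a)": (0.25, 0.25, 0.25, 4, 4, 2, 1),
        "FaTIP(b)": (0.25, 0.25, 1, 1, 1, 2, 2),
        "clathrin": (1,) * 7,
        "CHP3": (1,) * 7,
        "EF1a": (1, 2, 0.5, 1, 4, 0.5, 2),
        "GAPDH": (2, 0.5, 1, 4, 1, 2, 0.5),
    }
    expression = {(tissue, target): float(profiles[target][i])
                  for i, tissue in enumerate(TISSUES) for target in targets}
    return QpcrSimDesign(targets=targets,
                         reference_targets=("clathrin", "CHP3"),
                         samples=samples, expression=expression,
                         noise_sigma=noise_sigma, seed=seed)


def _logistic_curve(cycles: np.ndarray, efficiency: float, c_half: float,
                    plateau: float) -> np.ndarray:
    k = math.log(efficiency)
    return plateau / (1.0 + np.exp(-k * (cycles - c_half)))


def simulate_qpcr_run(design: QpcrSimDesign) -> list[WellRecord]:
    """Simulate all wells of a plate (sample + noRT per sample/target,
    one NTC per target), deterministically for the design's seed.

    Amplification follows a logistic curve whose exponential phase has
    fold-change E per cycle; the midpoint cycle encodes the programmed
    expression level, so a 2x level difference shifts Cq by exactly
    log_E(2) cycles.  noRT wells amplify ``nort_offset`` cycles late.
    """
    rng = np.random.default_rng(design.seed)
    cycles = np.arange(1, design.cycles + 1, dtype=float)
    wells: list[WellRecord] = []

    def emit(sample: str, target: str, well_type: str, c_half: float | None):
        sig = np.zeros_like(cycles)
        if c_half is not None:
            sig = _logistic_curve(cycles, design.targets[target], c_half,
                                  design.plateau)
        noise = rng.lognormal(0.0, design.noise_sigma, size=cycles.shape) \
            if design.noise_sigma > 0 else 1.0
        base_jitter = rng.lognormal(0.0, design.noise_sigma / 2,
                                    size=cycles.shape) \
            if design.noise_sigma > 0 else 1.0
        f = design.baseline * base_jitter + sig * noise
        wells.append(WellRecord(sample, target, well_type,
                                tuple(float(x) for x in f)))

    for sample, tissue in design.samples:
        for target, eff in design.targets.items():
            level = design.expression[(tissue, target)]
            c_half = design.ch_half - math.log(level) / math.log(eff)
            emit(sample, target, "sample", c_half)
            emit(sample, target, "noRT", c_half + design.offset_for(sample))
    for target in design.targets:
        emit("NTC", target, "NTC", None)
    return wells


def wells_to_frame(wells: list[WellRecord]):
    """Long-format (sample, target, well_type, cycle, fluorescence) frame."""
    import pandas as pd

    rows = [(w.sample, w.target, w.well_type, c + 1, f)
            for w in wells for c, f in enumerate(w.fluorescence)]
    return pd.DataFrame(rows, columns=["sample", "target", "well_type",
                                       "cycle", "fluorescence"])


def wells_from_frame(frame) -> list[WellRecord]:
    wells = []
    for (sample, target, wtype), grp in frame.groupby(
            ["sample", "target", "well_type"], sort=False):
        grp = grp.sort_values("cycle")
        wells.append(WellRecord(str(sample), str(target), str(wtype),
                                tuple(float(x) for x in grp["fluorescence"])))
    return wells
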