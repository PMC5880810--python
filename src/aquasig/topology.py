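"""Hydropathy-based transmembrane topology prediction.

Plant aquaporins have six transmembrane (TM) helices connected by five
loops (A-E); the two NPA motifs sit in loops B and E.  This module
predicts helices as maximal runs of high Kyte-Doolittle hydropathy and
labels the inter-helical loops, a deliberately simple stand-in for HMM
topology predictors.  Because hydropathy prediction can misplace
conserved residues near helix boundaries (the conserved loop-D Leu is a
known case), topology output is only used for sanity checks and is
never the coordinate anchor for residue extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .errors import AnalysisError
from .seqio import ProteinRecord

DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.6
DEFAULT_MIN_LEN = 15
DEFAULT_MERGE_GAP = 3

LOOP_LETTERS = "ABCDE"


@dataclass(frozen=True)
class TopologyMap:
    """Predicted helix intervals, loop labels and per-residue states."""

    sequence_id: str
    length: int
    helices: tuple[tuple[int, int], ...]      # 1-based inclusive, sorted
    mean_hydropathy: tuple[float, ...]        # one per helix
    labels: tuple[str, ...]                   # per-residue state labels

    @property
    def n_helices(self) -> int:
        return len(self.helices)

    @property
    def loops(self) -> tuple[tuple[str, int, int], ...]:
        """(label, start, end) of each inter-helix loop."""
        out = []
        for k in range(len(self.helices) - 1):
            start = self.helices[k][1] + 1
            end = self.helices[k + 1][0] - 1
            label = (f"loop{LOOP_LETTERS[k]}" if len(self.helices) == 6
                     else f"loop{k + 1}")
            out.append((label, start, end))
        return tuple(out)

    def state_at(self, coord: int) -> str:
        return self.labels[coord - 1]


def hydropathy_profile(record: ProteinRecord, window: int = DEFAULT_WINDOW
                       ) -> np.ndarray:
    """Sliding-window mean Kyte-Doolittle hydropathy, one score per residue.

    Gap characters are stripped first; ends use shrunken (clipped)
    windows so the output length equals the ungapped sequence length.
    ``X`` scores 0 (indifferent).
    """
    seq = record.seq.replace("-", "")
    if len(seq) < 5:
        raise AnalysisError(f"{record.id}: sequence shorter than 5 residues")
    if window < 5 or window % 2 == 0:
        raise AnalysisError("window must be odd and >= 5")
    if len(seq) < window:
        raise AnalysisError(f"{record.id}: sequence shorter than window")
    values = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in seq])
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n = len(seq)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def predict_tm_helices(profile: np.ndarray,
                       sequence_id: str = "",
                       threshold: float = DEFAULT_THRESHOLD,
                       min_len: int = DEFAULT_MIN_LEN,
                       merge_gap: int = DEFAULT_MERGE_GAP) -> TopologyMap:
    """Call TM helices as thresholded hydropathy runs.

    Maximal runs of ``profile >= threshold`` are merged when separated by
    at most ``merge_gap`` residues and kept when at least ``min_len``
    long.  Zero helices is a valid outcome.
    """
    profile = np.asarray(profile, dtype=float)
    n = len(profile)
    above = profile >= threshold
    runs: list[list[int]] = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    helices = tuple((a + 1, b + 1) for a, b in merged if b - a + 1 >= min_len)
    means = tuple(float(profile[a - 1:b].mean()) for a, b in helices)

    labels = ["N-term"] * n
    for k, (a, b) in enumerate(helices, 1):
        for p in range(a - 1, b):
            labels[p] = f"TM{k}"
    for k in range(len(helices) - 1):
        lab = (f"loop{LOOP_LETTERS[k]}" if len(helices) == 6 else f"loop{k + 1}")
        for p in range(helices[k][1], helices[k + 1][0] - 1):
            labels[p] = lab
    if helices:
        for p in range(helices[-1][1], n):
            labels[p] = "C-term"
    return TopologyMap(sequence_id=sequence_id, length=n, helices=helices,
                       mean_hydropathy=means, labels=tuple(labels))


@dataclass(frozen=True)
class NpaTopologyReport:
    """Where the NPA motifs fall relative to the predicted topology."""

    npa1_state: str | None
    npa2_state: str | None
    npa1_in_loopB: bool
    npa2_in_loopE: bool
    warnings: tuple[str, ...]


def locate_npa_in_topology(topology: TopologyMap,
                           npa_hits: list[tuple[int, str]]) -> NpaTopologyReport:
    """Check that the first NPA lies in loop B and the second in loop E.

    A mismatch is reported as a warning, not an error: hydropathy-based
    topology can shift helix boundaries by a few residues.
    """
    warnings: list[str] = []
    states: list[str | None] = [None, None]
    for k in range(2):
        if k < len(npa_hits):
            start, motif = npa_hits[k]
            states[k] = topology.state_at(start)
        else:
            warnings.append(f"missing NPA motif #{k + 1}")
    in_b = states[0] == "loopB"
    in_e = states[1] == "loopE"
    if states[0] is not None and not in_b:
        warnings.append(f"first NPA predicted in {states[0]}, expected loopB")
    if states[1] is not None and not in_e:
        warnings.append(f"second NPA predicted in {states[1]}, expected loopE")
    return NpaTopologyReport(npa1_state=states[0], npa2_state=states[1],
                             npa1_in_loopB=in_b, npa2_in_loopE=in_e,
                             warnings=tuple(warnings))
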