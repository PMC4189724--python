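"""Plant miRNA target scoring, transcriptome scanning and cleavage mapping.

The scoring scheme follows the classical plant small-RNA target rules:
mismatches cost 1.0, G:U wobbles 0.5 and gaps 2.0, with penalties doubled at
miRNA positions 2-13 (the seed-proximal region counted from the miRNA 5'
end); an alignment is reported when its total penalty is at or below the
cutoff (default 4.0).  Scanning is ungapped-first with single-gap extension:
each candidate site is the reverse-complement-oriented window, optionally
with one unpaired base on either strand.

The guided cleavage site falls between the transcript positions pairing with
miRNA positions 10 and 11.  Because the duplex is antiparallel, transcript
coordinates descend as miRNA positions ascend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from srnapipe.seqs import validate_nucleotides

MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
GAP_PENALTY = 2.0
CORE_START, CORE_END = 2, 13  # miRNA positions with doubled penalties (1-based)
DEFAULT_CUTOFF = 4.0

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U in RNA space


def _pair_state(mirna_base: str, target_base: str) -> str:
    if (mirna_base, target_base) in _WC:
        return "match"
    if (mirna_base, target_base) in _WOBBLE:
        return "wobble"
    return "mismatch"


def _position_weight(position: int) -> float:
    return 2.0 if CORE_START <= position <= CORE_END else 1.0


@dataclass
class TargetAlignment:
    """A scored miRNA:mRNA duplex.

    ``states`` holds one entry per alignment column as
    ``(mirna_position, transcript_position, state)`` with 1-based positions;
    a gapped column carries ``None`` on the gapped side.
    """

    mirna: str
    transcript_id: str
    site: str
    start: int  # 1-based inclusive transcript coordinates of the site
    end: int
    states: list[tuple[int | None, int | None, str]] = field(default_factory=list)
    score: float = 0.0

    def predicted_cleavage(self) -> tuple[int, int]:
        return predict_cleavage(self)


def score_target(
    mirna: str,
    window: str,
    *,
    transcript_id: str = "window",
    window_start: int = 1,
    gap: tuple[str, int] | None = None,
) -> TargetAlignment:
    """Score one miRNA against one transcript window.

    ``gap`` optionally introduces a single unpaired base: ``("target", k)``
    leaves the k-th window base (1-based) unpaired (a target bulge; the
    window is one base longer than the miRNA), while ``("mirna", k)`` leaves
    miRNA position k unpaired (the window is one base shorter).  The gap is
    charged at the miRNA position adjacent to it.
    """
    mirna = validate_nucleotides(mirna)
    window = validate_nucleotides(window)
    n = len(mirna)
    expected = n + (1 if gap and gap[0] == "target" else -1 if gap else 0)
    if len(window) != expected:
        raise ValueError(f"window length {len(window)}; expected {expected}")
    states: list[tuple[int | None, int | None, str]] = []
    score = 0.0
    # Build the aligned columns walking the miRNA 5'->3' and the window
    # 3'->5' (antiparallel duplex).
    t_index = len(window)  # 1-based position within the window, descending
    m_pos = 1
    gap_kind, gap_at = gap if gap else (None, -1)
    while m_pos <= n or t_index >= 1:
        if gap_kind == "target" and t_index == gap_at:
            charge_at = min(m_pos, n)
            score += GAP_PENALTY * _position_weight(charge_at)
            states.append((None, window_start + t_index - 1, "gap"))
            t_index -= 1
            continue
        if gap_kind == "mirna" and m_pos == gap_at:
            score += GAP_PENALTY * _position_weight(m_pos)
            states.append((m_pos, None, "gap"))
            m_pos += 1
            continue
        if m_pos > n or t_index < 1:
            raise ValueError("gap specification inconsistent with window length")
        state = _pair_state(mirna[m_pos - 1], window[t_index - 1])
        if state == "mismatch":
            score += MISMATCH_PENALTY * _position_weight(m_pos)
        elif state == "wobble":
            score += WOBBLE_PENALTY * _position_weight(m_pos)
        states.append((m_pos, window_start + t_index - 1, state))
        m_pos += 1
        t_index -= 1
    return TargetAlignment(
        mirna=mirna,
        transcript_id=transcript_id,
        site=window,
        start=window_start,
        end=window_start + len(window) - 1,
        states=states,
        score=score,
    )


def _best_alignment_at(
    mirna: str, transcript: str, transcript_id: str, start0: int, cutoff: float
) -> TargetAlignment | None:
    """Best (lowest-score) alignment among the ungapped and single-gap forms."""
    n = len(mirna)
    best: TargetAlignment | None = None
    # ungapped
    if start0 + n <= len(transcript):
        aln = score_target(
            mirna,
            transcript[start0 : start0 + n],
            transcript_id=transcript_id,
            window_start=start0 + 1,
        )
        if aln.score <= cutoff:
            best = aln
    # one target bulge (window n+1)
    if start0 + n + 1 <= len(transcript):
        window = transcript[start0 : start0 + n + 1]
        for k in range(1, n + 2):
            aln = score_target(
                mirna,
                window,
                transcript_id=transcript_id,
                window_start=start0 + 1,
                gap=("target", k),
            )
            if aln.score <= cutoff and (best is None or aln.score < best.score):
                best = aln
    # one unpaired miRNA base (window n-1)
    if start0 + n - 1 <= len(transcript):
        window = transcript[start0 : start0 + n - 1]
        for k in range(1, n + 1):
            aln = score_target(
                mirna,
                window,
                transcript_id=transcript_id,
                window_start=start0 + 1,
                gap=("mirna", k),
            )
            if aln.score <= cutoff and (best is None or aln.score < best.score):
                best = aln
    return best


def scan_transcriptome(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    cutoff: float = DEFAULT_CUTOFF,
) -> dict[str, list[TargetAlignment]]:
    """All target sites at or under the cutoff, per miRNA.

    Hits are sorted by score, then transcript id, then coordinate.  A window
    is reported once with its best gapped/ungapped alignment.
    """
    results: dict[str, list[TargetAlignment]] = {}
    for mid, mseq in mirnas.items():
        mseq = validate_nucleotides(mseq)
        if not 20 <= len(mseq) <= 24:
            raise ValueError(f"miRNA {mid!r} length {len(mseq)} outside 20-24 nt")
        hits = []
        for tid, tseq in transcripts.items():
            tseq = validate_nucleotides(tseq)
            for start0 in range(0, len(tseq)):
                aln = _best_alignment_at(mseq, tseq, tid, start0, cutoff)
                if aln is not None:
                    hits.append(aln)
        hits.sort(key=lambda a: (a.score, a.transcript_id, a.start))
        results[mid] = hits
    return results


def predict_cleavage(alignment: TargetAlignment) -> tuple[int, int]:
    """Transcript positions pairing miRNA positions 10 and 11, ascending.

    Raises when a gap falls on (or between) those positions, which leaves
    the site indeterminate.
    """
    by_mirna_pos = {}
    for m_pos, t_pos, state in alignment.states:
        if m_pos in (10, 11):
            if state == "gap" or t_pos is None:
                raise ValueError("indeterminate site: gap at miRNA positions 10-11")
            by_mirna_pos[m_pos] = t_pos
    for m_low, t_pos, state in alignment.states:
        if m_low is None and state == "gap":
            # a target bulge between the columns for positions 10 and 11
            if 10 in by_mirna_pos and 11 in by_mirna_pos:
                if by_mirna_pos[11] < t_pos < by_mirna_pos[10]:
                    raise ValueError("indeterminate site: gap at miRNA positions 10-11")
    if 10 not in by_mirna_pos or 11 not in by_mirna_pos:
        raise ValueError("alignment does not cover miRNA positions 10-11")
    pair = (by_mirna_pos[11], by_mirna_pos[10])
    return (min(pair), max(pair))


def hit_counts(results: Mapping[str, Sequence[TargetAlignment]]) -> dict[str, int]:
    return {mid: len(hits) for mid, hits in results.items()}
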