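"""Novel-miRNA discovery from unannotated mapped tags.

Unannotated tags are clustered on the genome, each cluster is expanded into a
precursor window, the window is folded, and the candidate is screened with
miRNA-precursor criteria: a 20-23 nt mature arm, more than five reads in at
least one library, a clean mature/star duplex (at least ``min_paired`` of the
mature bases paired, asymmetric bulges of at most ``max_bulge`` nt, the
mature arm not spanning the terminal loop) and a folding energy of at most
``max_mfe`` kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from srnapipe.annotation import GenomeHit
from srnapipe.fold import dotbracket_to_pairs, fold_hairpin, pairs_to_partner
from srnapipe.seqs import revcomp

DEFAULT_FLANK = 150
DEFAULT_CLUSTER_GAP = 30


@dataclass
class PrecursorWindow:
    scaffold: str
    start: int
    end: int
    strand: str
    tag_hits: list[GenomeHit] = field(default_factory=list)

    @property
    def locus(self) -> str:
        return f"{self.scaffold}:{self.start}:{self.end}"


@dataclass
class HairpinCandidate:
    """A folded precursor window with its mature/star arms and screening flags."""

    window: PrecursorWindow
    precursor: str
    structure: str
    mfe: float
    mature: str
    mature_offset: int  # 0-based offset of the mature arm within the precursor
    mature_counts: dict[str, int]
    arm: str = "?"  # 5p / 3p relative to the terminal loop
    star: str = ""
    star_observed: bool = False
    length_ok: bool = False
    count_ok: bool = False
    duplex_ok: bool = False
    energy_ok: bool = False

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.precursor):
            raise ValueError("structure/precursor length mismatch")
        if self.mfe > 0:
            raise ValueError("positive MFE")
        if self.precursor[self.mature_offset : self.mature_offset + len(self.mature)] != self.mature:
            raise ValueError("mature arm is not a substring of the precursor")

    @property
    def accepted(self) -> bool:
        return self.length_ok and self.count_ok and self.duplex_ok and self.energy_ok


def extract_candidates(
    hits: Iterable[GenomeHit],
    genome: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
    cluster_gap: int = DEFAULT_CLUSTER_GAP,
) -> list[PrecursorWindow]:
    """Merge tag hits into clusters and expand each into a precursor window.

    Windows are clipped at scaffold edges; tags closer than ``cluster_gap``
    on the same scaffold and strand share a window.
    """
    by_group: dict[tuple[str, str], list[GenomeHit]] = {}
    for hit in hits:
        by_group.setdefault((hit.scaffold, hit.strand), []).append(hit)
    windows: list[PrecursorWindow] = []
    for (scaffold, strand), group in sorted(by_group.items()):
        group.sort(key=lambda h: (h.start, h.end))
        cluster: list[GenomeHit] = []
        cluster_end = -1
        for hit in group + [None]:  # sentinel flushes the last cluster
            if hit is not None and (not cluster or hit.start - cluster_end - 1 <= cluster_gap):
                cluster.append(hit)
                cluster_end = max(cluster_end, hit.end)
                continue
            if cluster:
                start = max(1, min(h.start for h in cluster) - flank)
                end = min(len(genome[scaffold]), cluster_end + flank)
                windows.append(PrecursorWindow(scaffold, start, end, strand, cluster))
            if hit is not None:
                cluster = [hit]
                cluster_end = hit.end
        cluster = []
    return windows


def _window_sequence(window: PrecursorWindow, genome: Mapping[str, str]) -> str:
    sub = genome[window.scaffold][window.start - 1 : window.end]
    return sub if window.strand == "+" else revcomp(sub)


def _mature_in_window(window: PrecursorWindow, hit: GenomeHit) -> int:
    """0-based offset of a hit's tag within the (strand-oriented) window."""
    if window.strand == "+":
        return hit.start - window.start
    return window.end - hit.end


def build_candidate(
    window: PrecursorWindow,
    genome: Mapping[str, str],
    tag_counts: Mapping[str, Mapping[str, int]],
    backend: Callable | None = None,
) -> HairpinCandidate:
    """Fold a window and pick its mature arm.

    The most-abundant tag in the cluster becomes the mature candidate; ties
    break towards the 5'-most tag.
    """
    precursor = _window_sequence(window, genome)
    structure, mfe = fold_hairpin(precursor, backend=backend)
    ranked = sorted(
        window.tag_hits,
        key=lambda h: (-sum(tag_counts.get(h.tag, {}).values()), _mature_in_window(window, h)),
    )
    best = ranked[0]
    offset = _mature_in_window(window, best)
    partner = pairs_to_partner(len(precursor), dotbracket_to_pairs(structure))
    candidate = HairpinCandidate(
        window=window,
        precursor=precursor,
        structure=structure,
        mfe=mfe,
        mature=best.tag,
        mature_offset=offset,
        mature_counts=dict(tag_counts.get(best.tag, {})),
    )
    partners = [partner[k] for k in range(offset, offset + len(best.tag)) if partner[k] != -1]
    if partners:
        star_start, star_end = min(partners), max(partners)
        candidate.star = precursor[star_start : star_end + 1]
        candidate.arm = "5p" if star_start > offset else "3p"
        star_tags = {
            h.tag for h in window.tag_hits if h.tag != best.tag
        }
        candidate.star_observed = any(t in candidate.star for t in star_tags)
    return candidate


def _duplex_ok(candidate: HairpinCandidate, min_paired: int, max_bulge: int) -> bool:
    partner = pairs_to_partner(
        len(candidate.precursor), dotbracket_to_pairs(candidate.structure)
    )
    lo = candidate.mature_offset
    hi = lo + len(candidate.mature)
    paired = [(k, int(partner[k])) for k in range(lo, hi) if partner[k] != -1]
    if len(paired) < min_paired:
        return False
    # mature pairing with itself means the arm spans the terminal loop
    if any(lo <= p < hi for _, p in paired):
        return False
    # antiparallel duplex: partners must descend as mature positions ascend
    for (k1, p1), (k2, p2) in zip(paired, paired[1:]):
        if p2 >= p1:
            return False
        if abs((k2 - k1 - 1) - (p1 - p2 - 1)) > max_bulge:
            return False
    return True


def screen_candidates(
    candidates: Iterable[HairpinCandidate],
    *,
    min_mature: int = 20,
    max_mature: int = 23,
    min_count: int = 5,
    min_paired: int = 16,
    max_bulge: int = 4,
    max_mfe: float = -18.0,
) -> list[HairpinCandidate]:
    """Flag every candidate and return the accepted set.

    Acceptance requires all four flags; the read-count rule is "strictly more
    than ``min_count`` reads in at least one library".  Candidates sharing a
    mature sequence are deduplicated (highest total count wins), making the
    result independent of input order.
    """
    flagged = []
    for cand in candidates:
        cand.length_ok = min_mature <= len(cand.mature) <= max_mature
        cand.count_ok = any(c > min_count for c in cand.mature_counts.values())
        cand.energy_ok = cand.mfe <= max_mfe
        cand.duplex_ok = _duplex_ok(cand, min_paired, max_bulge)
        if cand.accepted:
            flagged.append(cand)
    best_by_mature: dict[str, HairpinCandidate] = {}
    for cand in sorted(
        flagged,
        key=lambda c: (-sum(c.mature_counts.values()), c.window.locus, c.mature),
    ):
        best_by_mature.setdefault(cand.mature, cand)
    return sorted(best_by_mature.values(), key=lambda c: (c.window.locus, c.mature))


@dataclass
class NovelMirnaStats:
    n_candidates: int
    mfe_mean: float
    mfe_sd: float
    five_prime_u_fraction: float


def novel_mirna_stats(accepted: Sequence[HairpinCandidate]) -> NovelMirnaStats:
    """Candidate count, MFE mean +/- sample sd, and 5'U start fraction."""
    if not accepted:
        raise ValueError("empty candidate set")
    mfes = [c.mfe for c in accepted]
    mean = sum(mfes) / len(mfes)
    sd = (
        math.sqrt(sum((m - mean) ** 2 for m in mfes) / (len(mfes) - 1))
        if len(mfes) > 1
        else 0.0
    )
    five_u = sum(1 for c in accepted if c.mature.startswith("T")) / len(accepted)
    return NovelMirnaStats(len(accepted), mean, sd, five_u)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving dinucleotide composition.

    Used to build decoy precursors for screening-specificity checks.
    """
    if len(seq) < 3:
        return seq
    chars = list(seq)
    edges: dict[str, list[str]] = {}
    for a, b in zip(chars, chars[1:]):
        edges.setdefault(a, []).append(b)
    vertices = list(edges)
    last = chars[-1]
    for _ in range(2000):
        # pick a candidate last-edge for every non-terminal vertex
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        # the chosen last edges must lead every vertex to the terminal one
        ok = True
        for v in last_edge:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if not ok:
            continue
        shuffled_edges = {}
        for v in vertices:
            rest = list(edges[v])
            if v in last_edge:
                rest.remove(last_edge[v])
            rng.shuffle(rest)
            if v in last_edge:
                rest.append(last_edge[v])
            shuffled_edges[v] = rest
        out = [chars[0]]
        cur = chars[0]
        pos = {v: 0 for v in vertices}
        for _step in range(len(chars) - 1):
            nxt = shuffled_edges[cur][pos[cur]]
            pos[cur] += 1
            out.append(nxt)
            cur = nxt
        return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian ordering")
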