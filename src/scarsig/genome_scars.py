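"""Copy-number profile smoothing and genomic-scar scores (HRD-LOH, LST).

Profiles are first smoothed against oversegmentation: adjacent segments with
identical rounded (total, A, B) states whose real copy numbers differ by at
most 0.3 are merged, and segments below 3 Mb are absorbed into their more
similar neighbor. HRD-LOH counts LOH segments longer than 15 Mb but shorter
than their chromosome; LST counts copy-number state switches between flanking
segments longer than 10 Mb that do not correspond to whole chromosome arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CnSegment",
    "Arm",
    "ScarScores",
    "smooth_profile",
    "count_lst",
    "count_hrd_loh",
    "scar_scores",
]

MB = 1_000_000


@dataclass
class CnSegment:
    """One segment of an allele-specific copy-number profile."""

    chrom: str
    start: int
    end: int
    total_cn: int
    a_cn: int
    b_cn: int
    real_cn: float | None = None
    length_bp: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must not exceed end")
        if not (self.a_cn >= self.b_cn >= 0):
            raise ValueError("allele copies must satisfy A >= B >= 0")
        if self.a_cn + self.b_cn != self.total_cn:
            raise ValueError("A + B must equal total copy number")
        if self.real_cn is None:
            self.real_cn = float(self.total_cn)
        if self.length_bp is None:
            self.length_bp = self.end - self.start + 1

    @property
    def state(self) -> tuple[int, int, int]:
        return (self.total_cn, self.a_cn, self.b_cn)


@dataclass(frozen=True)
class Arm:
    chrom: str
    name: str           # "p" or "q"
    start: int
    end: int


@dataclass
class ScarScores:
    hrd_loh: int
    lst: int
    hrd_events: list[CnSegment] = field(default_factory=list)
    lst_breakpoints: list[tuple[str, int]] = field(default_factory=list)


def _by_chrom(profile: Iterable[CnSegment]) -> dict[str, list[CnSegment]]:
    chroms: dict[str, list[CnSegment]] = {}
    for seg in profile:
        chroms.setdefault(seg.chrom, []).append(seg)
    for segs in chroms.values():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if a.end >= b.start:
                raise ValueError(f"overlapping segments on {a.chrom}")
    return chroms


def _merge(a: CnSegment, b: CnSegment, state_from: CnSegment | None = None) -> CnSegment:
    donor = state_from if state_from is not None else a
    la, lb = a.length_bp, b.length_bp
    return CnSegment(
        chrom=a.chrom,
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        total_cn=donor.total_cn,
        a_cn=donor.a_cn,
        b_cn=donor.b_cn,
        real_cn=(a.real_cn * la + b.real_cn * lb) / (la + lb),
        length_bp=la + lb,
    )


def _merge_same_state(segs: list[CnSegment], max_dev: float) -> list[CnSegment]:
    changed = True
    while changed:
        changed = False
        out: list[CnSegment] = []
        for seg in segs:
            if (
                out
                and out[-1].state == seg.state
                and abs(out[-1].real_cn - seg.real_cn) <= max_dev
            ):
                out[-1] = _merge(out[-1], seg)
                changed = True
            else:
                out.append(seg)
        segs = out
    return segs


def _absorb_small(segs: list[CnSegment], min_len: int) -> list[CnSegment]:
    while len(segs) > 1:
        small = [i for i, s in enumerate(segs) if s.length_bp < min_len]
        if not small:
            break
        i = min(small, key=lambda j: segs[j].length_bp)
        seg = segs[i]
        left = segs[i - 1] if i > 0 else None
        right = segs[i + 1] if i < len(segs) - 1 else None
        if left is None:
            neighbor, j = right, i + 1
        elif right is None:
            neighbor, j = left, i - 1
        else:
            dl = abs(left.real_cn - seg.real_cn)
            dr = abs(right.real_cn - seg.real_cn)
            neighbor, j = (left, i - 1) if dl <= dr else (right, i + 1)
        merged = _merge(seg, neighbor, state_from=neighbor)
        lo, hi = min(i, j), max(i, j)
        segs = segs[:lo] + [merged] + segs[hi + 1 :]
    return segs


def smooth_profile(
    profile: Sequence[CnSegment],
    max_dev: float = 0.3,
    min_len: int = 3 * MB,
) -> list[CnSegment]:
    """Merge equal-state neighbors and absorb sub-``min_len`` segments.

    Both passes are iterated to a fixpoint per chromosome; a chromosome
    reduced to a single segment is kept regardless of its length.
    """
    result: list[CnSegment] = []
    for _, segs in sorted(_by_chrom(profile).items()):
        prev = None
        while prev != [(s.start, s.end, s.state, s.real_cn) for s in segs]:
            prev = [(s.start, s.end, s.state, s.real_cn) for s in segs]
            segs = _merge_same_state(segs, max_dev)
            segs = _absorb_small(segs, min_len)
        result.extend(segs)
    return result


def _is_full_arm(seg: CnSegment, arms: Sequence[Arm], tol: int) -> bool:
    return any(
        arm.chrom == seg.chrom
        and abs(seg.start - arm.start) <= tol
        and abs(seg.end - arm.end) <= tol
        for arm in arms
    )


def _near_centromere(chrom: str, pos: int, arms: Sequence[Arm], tol: int) -> bool:
    for arm in arms:
        if arm.chrom == chrom and arm.name == "p" and abs(pos - arm.end) <= tol:
            return True
    return False


def count_lst(
    profile: Sequence[CnSegment],
    arms: Sequence[Arm],
    min_seg: int = 10 * MB,
    arm_tol: int = 3 * MB,
    both_flanks: bool = True,
) -> list[tuple[str, int]]:
    """Breakpoints counted as large-scale state transitions.

    A breakpoint counts when the flanking segments (both, or at least one if
    ``both_flanks`` is False) exceed ``min_seg``, the (total, A, B) states
    differ, neither flank coincides with a full chromosome arm (within
    ``arm_tol``), and the breakpoint does not sit at the centromere.
    """
    if not arms:
        raise ValueError("arm map required for LST counting")
    breakpoints: list[tuple[str, int]] = []
    for chrom, segs in sorted(_by_chrom(profile).items()):
        for left, right in zip(segs, segs[1:]):
            big = (
                left.length_bp > min_seg and right.length_bp > min_seg
                if both_flanks
                else left.length_bp > min_seg or right.length_bp > min_seg
            )
            if not big or left.state == right.state:
                continue
            if _is_full_arm(left, arms, arm_tol) or _is_full_arm(right, arms, arm_tol):
                continue
            if _near_centromere(chrom, left.end, arms, arm_tol):
                continue
            breakpoints.append((chrom, left.end))
    return breakpoints


def count_hrd_loh(
    profile: Sequence[CnSegment],
    chrom_lengths: Mapping[str, int],
    min_len: int = 15 * MB,
    single_copy_mode: bool = False,
) -> list[CnSegment]:
    """Segments counted toward the HRD-LOH score.

    LOH segments (B = 0 with at least one remaining copy) longer than
    ``min_len`` but shorter than their chromosome. In ``single_copy_mode``
    (profiles without allele-specific copies) the criterion becomes
    total copy number = 1.
    """
    events: list[CnSegment] = []
    for seg in profile:
        if seg.chrom not in chrom_lengths:
            raise KeyError(f"no chromosome length for {seg.chrom}")
        if single_copy_mode:
            is_loh = seg.total_cn == 1
        else:
            is_loh = seg.b_cn == 0 and seg.total_cn >= 1
        if is_loh and min_len < seg.length_bp < chrom_lengths[seg.chrom]:
            events.append(seg)
    return events


def scar_scores(
    profile: Sequence[CnSegment],
    arms: Sequence[Arm],
    chrom_lengths: Mapping[str, int],
    smooth: bool = True,
    single_copy_mode: bool = False,
    **kwargs,
) -> ScarScores:
    """Smooth a profile and compute both scar scores."""
    segs = smooth_profile(profile) if smooth else list(profile)
    hrd = count_hrd_loh(segs, chrom_lengths, single_copy_mode=single_copy_mode)
    lst = count_lst(segs, arms)
    return ScarScores(
        hrd_loh=len(hrd), lst=len(lst), hrd_events=hrd, lst_breakpoints=lst
    )
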