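"""The simplification sequence of a ploidy profile.

Starting from a profile in descending order, one step is applied repeatedly
until the profile is simple.  With ``alpha = m_1 - m_2``:

* ``alpha == 0`` (merge, line 6): the first component is deleted; the taxon
  that indexed it is recorded together with the surviving equal component.
* ``alpha > 0`` (subtract, line 8 if ``alpha > m_2`` else line 10): the first
  component is replaced by ``alpha`` (its taxon label is retained) and the
  profile re-sorted.

Every step records enough provenance for the traceback module to reverse it.
The per-step line number matters because the exactness guarantee of the
closed formula requires that line 8 (``alpha > m_2``, i.e. ``m_1 > 2 m_2``)
never fires.
"""

from __future__ import annotations

from dataclasses import dataclass

from .netcore import PloidyProfile

__all__ = [
    "SimplificationStep",
    "SimplificationSequence",
    "simplification_sequence",
    "s_of",
    "c_of",
    "line8_fired",
]

LINE_MERGE = 6
LINE_BIG_SUBTRACT = 8
LINE_SMALL_SUBTRACT = 10


@dataclass(frozen=True)
class SimplificationStep:
    """One transformation between consecutive profiles.

    ``receiver_label`` indexed ``m_1`` at the step (for subtract steps its
    component becomes alpha; for merge steps it is removed), and
    ``donor_label`` indexed ``m_2`` (the merge survivor).
    """

    kind: str  # "merge" | "subtract"
    alpha: int
    line: int  # 6, 8 or 10
    receiver_label: str
    donor_label: str

    def __post_init__(self) -> None:
        if self.kind == "merge":
            assert self.alpha == 0 and self.line == LINE_MERGE
        else:
            assert self.kind == "subtract" and self.alpha >= 1
            assert self.line in (LINE_BIG_SUBTRACT, LINE_SMALL_SUBTRACT)


@dataclass(frozen=True)
class SimplificationSequence:
    """The full sequence of profiles from the input down to a simple one."""

    profiles: tuple[PloidyProfile, ...]
    steps: tuple[SimplificationStep, ...]

    def __post_init__(self) -> None:
        assert len(self.profiles) == len(self.steps) + 1

    @property
    def initial(self) -> PloidyProfile:
        return self.profiles[0]

    @property
    def terminal(self) -> PloidyProfile:
        return self.profiles[-1]

    @property
    def s(self) -> int:
        """Number of profiles other than the first."""
        return len(self.profiles) - 1

    @property
    def c(self) -> int:
        """Number of subtract steps (steps whose source had m_1 > m_2)."""
        return sum(1 for st in self.steps if st.kind == "subtract")

    @property
    def line8_fired(self) -> bool:
        """True iff some step had alpha > m_2 (equivalently m_1 > 2 m_2)."""
        return any(st.line == LINE_BIG_SUBTRACT for st in self.steps)


def _one_step(profile: PloidyProfile) -> tuple[PloidyProfile, SimplificationStep]:
    entries = list(profile.entries)
    (lab1, m1), (lab2, m2) = entries[0], entries[1]
    alpha = m1 - m2
    if alpha == 0:
        step = SimplificationStep(
            kind="merge", alpha=0, line=LINE_MERGE, receiver_label=lab1, donor_label=lab2
        )
        return PloidyProfile(tuple(entries[1:])), step
    line = LINE_BIG_SUBTRACT if alpha > m2 else LINE_SMALL_SUBTRACT
    step = SimplificationStep(
        kind="subtract", alpha=alpha, line=line, receiver_label=lab1, donor_label=lab2
    )
    rest = entries[1:]
    # re-insert (lab1, alpha) after all components of equal or larger value
    pos = 0
    while pos < len(rest) and rest[pos][1] >= alpha:
        pos += 1
    rest.insert(pos, (lab1, alpha))
    return PloidyProfile(tuple(rest)), step


def simplification_sequence(profile: PloidyProfile) -> SimplificationSequence:
    """Run the simplification to its simple terminal profile.

    Termination: every step strictly decreases the multiplicity tuple
    lexicographically (a merge shortens it with an equal prefix; a subtract
    lowers the maximum, since both m_2 and alpha are < m_1).
    """
    profiles = [profile]
    steps: list[SimplificationStep] = []
    cur = profile
    while not cur.is_simple:
        cur, step = _one_step(cur)
        profiles.append(cur)
        steps.append(step)
    return SimplificationSequence(profiles=tuple(profiles), steps=tuple(steps))


def s_of(seq: SimplificationSequence) -> int:
    return seq.s


def c_of(seq: SimplificationSequence) -> int:
    return seq.c


def line8_fired(seq: SimplificationSequence) -> bool:
    return seq.line8_fired
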