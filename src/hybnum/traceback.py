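"""Traceback: rebuild a realization of the input profile from its
simplification sequence.

Steps are reversed last-to-first, starting from a single network realizing
the terminal simple profile:

* a merge step is undone by expanding the surviving leaf into a cherry whose
  new leaf takes the removed taxon's label;
* a subtract step is undone by hybridizing the donor leaf into the receiver
  leaf, restoring ``m_1 = alpha + m_2``.

Each reversal adds exactly two vertices, so the result has
``a(terminal) + 2 s`` vertices; its hybrid number is the terminal network's
plus the number of subtract steps.
"""

from __future__ import annotations

from typing import NamedTuple

from .netcore import NetworkError, PhyloNetwork, PloidyProfile
from .simplify import SimplificationSequence, simplification_sequence

__all__ = ["build_N", "build_N_auto", "TracebackResult"]


class TracebackResult(NamedTuple):
    network: PhyloNetwork
    certified: bool  # was the terminal network a certified attainment?
    sequence: SimplificationSequence
    terminal_network: PhyloNetwork


def build_N(seq: SimplificationSequence, terminal_network: PhyloNetwork) -> PhyloNetwork:
    """Reverse ``seq`` starting from ``terminal_network``.

    The terminal network must be binary and realize the terminal profile
    with matching labels.  The input is not mutated.
    """
    terminal_network.require_valid()
    if not terminal_network.is_binary():
        raise NetworkError("terminal network must be binary")
    if not terminal_network.realizes(seq.terminal):
        raise NetworkError(
            f"terminal network realizes {terminal_network.path_count_vector()}, "
            f"not the terminal profile {dict(seq.terminal.entries)}"
        )
    net = terminal_network.copy()
    for step in reversed(seq.steps):
        if step.kind == "merge":
            # donor_label survived the merge; receiver_label was removed
            net.expand_cherry(step.donor_label, step.receiver_label)
        else:
            net.hybridize(donor_label=step.donor_label, receiver_label=step.receiver_label)
    return net


def build_N_auto(
    profile: PloidyProfile, search_limit: int = 512, budget: int | None = 12
) -> TracebackResult:
    """Simplify, obtain a terminal realization, and trace back.

    The terminal network comes from the exact attainment search when the
    terminal head is within ``search_limit`` (certified minimal), otherwise
    from the better of the B/D constructions (upper bound only).
    """
    from .hybridnumber import attain_simple

    seq = simplification_sequence(profile)
    terminal_net, certified = attain_simple(
        seq.terminal, search_limit=search_limit, budget=budget
    )
    network = build_N(seq, terminal_net)
    return TracebackResult(
        network=network, certified=certified, sequence=seq, terminal_network=terminal_net
    )
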