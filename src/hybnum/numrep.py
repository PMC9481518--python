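"""Integer representations backing the explicit network constructions.

Two representations matter: the binary (bitwise / exponent-vector) form of a
positive integer, and its prime factor decomposition with primes listed in
descending order.
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy

__all__ = [
    "BinaryRepresentation",
    "PrimeFactorization",
    "binary_representation",
    "p_of",
    "prime_factorization_desc",
    "ceil_log2",
    "FACTORIZATION_LIMIT",
]

#: Largest integer accepted by :func:`prime_factorization_desc`.  Profile
#: entries are biology-scale; anything bigger is rejected loudly rather than
#: silently churned through.
FACTORIZATION_LIMIT = 10**6


@dataclass(frozen=True)
class BinaryRepresentation:
    """Bitwise vector (most significant bit first, leading bit 1) and the
    strictly decreasing exponent vector (i_1, ..., i_q) with m = sum 2^i_j."""

    bitwise: tuple[int, ...]
    exponents: tuple[int, ...]

    @property
    def q(self) -> int:
        """Number of one-bits."""
        return len(self.exponents)

    @property
    def msb_exponent(self) -> int:
        """Position of the most significant bit (i_1)."""
        return self.exponents[0]

    def value(self) -> int:
        return sum(1 << e for e in self.exponents)


@dataclass(frozen=True)
class PrimeFactorization:
    """Ordered (prime, exponent) pairs with primes strictly descending."""

    factors: tuple[tuple[int, int], ...]

    def value(self) -> int:
        out = 1
        for p, a in self.factors:
            out *= p**a
        return out

    def __iter__(self):
        return iter(self.factors)


def binary_representation(m: int) -> BinaryRepresentation:
    """Both binary forms of ``m``: e.g. 11 -> bitwise (1,0,1,1), exponents (3,1,0)."""
    if not isinstance(m, int) or m < 1:
        raise ValueError(f"m must be a positive integer, got {m!r}")
    bits = tuple(int(b) for b in bin(m)[2:])
    exps = tuple(i for i, b in enumerate(reversed(bits)) if b)[::-1]
    return BinaryRepresentation(bitwise=bits, exponents=exps)


def p_of(m: int) -> int:
    """Number of one-bits of ``m`` excluding the leading one: popcount(m) - 1."""
    if not isinstance(m, int) or m < 1:
        raise ValueError(f"m must be a positive integer, got {m!r}")
    return m.bit_count() - 1


def prime_factorization_desc(m: int) -> PrimeFactorization:
    """Prime factor decomposition of ``m`` with primes in descending order."""
    if not isinstance(m, int) or m < 2:
        raise ValueError(f"m must be an integer >= 2, got {m!r}")
    if m > FACTORIZATION_LIMIT:
        raise ValueError(
            f"refusing to factor {m} > {FACTORIZATION_LIMIT}; ploidy numbers "
            "are expected to be small"
        )
    factored = sympy.factorint(m)
    factors = tuple(sorted(((int(p), int(a)) for p, a in factored.items()), reverse=True))
    return PrimeFactorization(factors=factors)


def ceil_log2(m: int) -> int:
    """Smallest h with 2**h >= m; a lower bound on the hybrid number of (m)."""
    if not isinstance(m, int) or m < 1:
        raise ValueError(f"m must be a positive integer, got {m!r}")
    return (m - 1).bit_length()
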