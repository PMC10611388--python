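"""Integer Laurent polynomials on a quarter-integer exponent lattice.

The Kauffman bracket lives in Z[A, A^-1] and the Jones polynomial in
Z[t^(1/2), t^(-1/2)] with A^(-4) = t; storing exponents as integer
multiples of t^(1/4) keeps every intermediate exact.  For knots the final
Jones polynomial always lands on integer powers of t.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["LaurentPoly"]


@dataclass(frozen=True)
class LaurentPoly:
    """Sparse Laurent polynomial; keys are exponents in units of t^(1/4)."""

    coeffs: tuple[tuple[int, int], ...] = ()  # sorted ((4*exp, coeff), ...)

    @staticmethod
    def from_dict(d: dict[int, int]) -> "LaurentPoly":
        items = tuple(sorted((e, c) for e, c in d.items() if c != 0))
        return LaurentPoly(items)

    @staticmethod
    def one() -> "LaurentPoly":
        return LaurentPoly(((0, 1),))

    def as_dict(self) -> dict[int, int]:
        return dict(self.coeffs)

    def __bool__(self) -> bool:
        return bool(self.coeffs)

    def __add__(self, other: "LaurentPoly") -> "LaurentPoly":
        d = self.as_dict()
        for e, c in other.coeffs:
            d[e] = d.get(e, 0) + c
        return LaurentPoly.from_dict(d)

    def __mul__(self, other: "LaurentPoly") -> "LaurentPoly":
        d: dict[int, int] = {}
        for e1, c1 in self.coeffs:
            for e2, c2 in other.coeffs:
                e = e1 + e2
                d[e] = d.get(e, 0) + c1 * c2
        return LaurentPoly.from_dict(d)

    def scale(self, coeff: int, quarter_exp: int = 0) -> "LaurentPoly":
        return LaurentPoly(
            tuple((e + quarter_exp, c * coeff) for e, c in self.coeffs)
        )

    def mirror(self) -> "LaurentPoly":
        """Substitute t -> 1/t."""
        return LaurentPoly(tuple(sorted((-e, c) for e, c in self.coeffs)))

    def evaluate_at_minus_one(self) -> int:
        """V(-1); defined when all exponents are integer powers of t."""
        total = 0
        for e, c in self.coeffs:
            if e % 4 != 0:
                raise ValueError("polynomial has fractional powers of t")
            total += c * (-1) ** ((e // 4) % 2)
        return total

    @property
    def is_palindromic(self) -> bool:
        return self == self.mirror()

    @property
    def span_quarters(self) -> int:
        if not self.coeffs:
            return 0
        exps = [e for e, _ in self.coeffs]
        return max(exps) - min(exps)

    def key(self) -> str:
        """Canonical text form, e.g. '-4:1,0:-1' (quarter-exponent:coeff)."""
        return ",".join(f"{e}:{c}" for e, c in self.coeffs)

    @staticmethod
    def from_key(key: str) -> "LaurentPoly":
        if not key:
            return LaurentPoly()
        items = []
        for part in key.split(","):
            e, c = part.split(":")
            items.append((int(e), int(c)))
        return LaurentPoly(tuple(sorted(items)))

    def __str__(self) -> str:
        if not self.coeffs:
            return "0"
        terms = []
        for e, c in sorted(self.coeffs, reverse=True):
            if e % 4 == 0:
                p = e // 4
                mono = "1" if p == 0 else ("t" if p == 1 else f"t^{p}")
            elif e % 2 == 0:
                mono = f"t^{e // 2}/2"
            else:
                mono = f"t^{e}/4"
            if mono == "1":
                term = f"{c:+d}"
            elif c == 1:
                term = f"+{mono}"
            elif c == -1:
                term = f"-{mono}"
            else:
                term = f"{c:+d}*{mono}"
            terms.append(term)
        s = "".join(terms)
        return s[1:] if s.startswith("+") else s
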