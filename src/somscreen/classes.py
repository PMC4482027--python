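"""Experimental classes of mice.

The study design crosses three binary factors:

* genotype -- wild-type littermate controls (``c``) vs the Ts65Dn partial
  trisomy model of Down syndrome (``t``);
* behavior -- context-shock (``CS``, stimulated to learn in context fear
  conditioning) vs shock-context (``SC``, shocked immediately, no learning);
* treatment -- saline (``s``) vs memantine (``m``) injection.

This yields eight classes, written with short codes such as ``c-CS-s``.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product

GENOTYPES = ("control", "trisomic")
BEHAVIORS = ("CS", "SC")
TREATMENTS = ("saline", "memantine")

_GENO_ALIASES = {
    "control": "control", "c": "control",
    "trisomic": "trisomic", "t": "trisomic", "ts65dn": "trisomic",
    "trisomy": "trisomic",
}
_BEHAV_ALIASES = {
    "cs": "CS", "c/s": "CS", "sc": "SC", "s/c": "SC",
}
_TREAT_ALIASES = {
    "saline": "saline", "s": "saline",
    "memantine": "memantine", "m": "memantine",
}


@dataclass(frozen=True, order=True)
class MouseClass:
    """One of the eight genotype x behavior x treatment classes."""

    genotype: str
    behavior: str
    treatment: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")

    @property
    def code(self) -> str:
        """Short label, e.g. ``c-CS-s`` for control / context-shock / saline."""
        return "-".join((self.genotype[0] if self.genotype == "control" else "t",
                         self.behavior,
                         self.treatment[0]))

    @classmethod
    def from_code(cls, code: str) -> "MouseClass":
        parts = code.strip().split("-")
        if len(parts) != 3:
            raise ValueError(f"unknown class code {code!r}")
        g, b, t = (p.lower() for p in parts)
        try:
            return cls(_GENO_ALIASES[g], _BEHAV_ALIASES[b], _TREAT_ALIASES[t])
        except KeyError:
            raise ValueError(f"unknown class code {code!r}") from None

    @classmethod
    def from_fields(cls, genotype: str, behavior: str, treatment: str) -> "MouseClass":
        try:
            return cls(
                _GENO_ALIASES[genotype.strip().lower()],
                _BEHAV_ALIASES[behavior.strip().lower()],
                _TREAT_ALIASES[treatment.strip().lower()],
            )
        except KeyError:
            raise ValueError(
                f"unknown class fields {(genotype, behavior, treatment)!r}"
            ) from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


#: The eight classes, in a fixed canonical order.
ALL_CLASSES: tuple[MouseClass, ...] = tuple(
    MouseClass(g, b, t) for g, b, t in product(GENOTYPES, BEHAVIORS, TREATMENTS)
)

CLASS_BY_CODE = {c.code: c for c in ALL_CLASSES}
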