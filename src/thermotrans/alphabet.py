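"""Canonical amino-acid alphabet and token conventions.

The 20 canonical residues are indexed 0-19 in the fixed order of
:data:`AA20`; the explicit end-of-sequence token occupies index 20.
Conditional sequence models emit probability vectors of length
:data:`N_TOKENS` over this token set.  ``X`` (unknown residue) is accepted
by validators when explicitly allowed but never appears in model output
distributions.
"""

from __future__ import annotations

AA20: str = "ACDEFGHIKLMNPQRSTVWY"
END_TOKEN: str = "*"
TOKENS: str = AA20 + END_TOKEN

N_RESIDUES: int = len(AA20)          # 20
END_INDEX: int = N_RESIDUES          # 20
N_TOKENS: int = len(TOKENS)          # 21

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA20)}
TOKEN_INDEX: dict[str, int] = {t: i for i, t in enumerate(TOKENS)}

GAP_CHARS = frozenset("-.")


class SequenceAlphabetError(ValueError):
    """A sequence contains a character outside the allowed alphabet."""


def validate_sequence(seq: str, *, allow_x: bool = False, name: str = "sequence") -> str:
    """Return ``seq`` uppercased, raising if any residue is non-canonical.

    Parameters
    ----------
    seq:
        Protein string to check.
    allow_x:
        Permit the unknown-residue placeholder ``X``.
    name:
        Label used in error messages.
    """
    up = seq.upper()
    allowed = set(AA20) | ({"X"} if allow_x else set())
    for pos, ch in enumerate(up):
        if ch not in allowed:
            raise SequenceAlphabetError(
                f"{name}: non-canonical residue {ch!r} at position {pos}"
            )
    return up


def encode(seq: str) -> list[int]:
    """Map a residue string to token indices, raising on unknown tokens."""
    try:
        return [TOKEN_INDEX[ch] for ch in seq]
    except KeyError as exc:
        bad = exc.args[0]
        raise SequenceAlphabetError(
            f"token {bad!r} at position {seq.index(bad)} is outside the model alphabet"
        ) from exc
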