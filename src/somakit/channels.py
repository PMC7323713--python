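"""The fixed 96-channel trinucleotide substitution alphabet.

Channel order (bit-exact across the package): substitution classes in the
order C>A, C>G, C>T, T>A, T>C, T>G; within each class the 5' base then the 3'
base, each cycling through A, C, G, T.  Labels read ``A[C>A]A`` ...
``T[T>G]T``.  Substitutions observed on the purine strand are
reverse-complemented onto the pyrimidine strand before channel assignment.
"""

from __future__ import annotations

from .records import COMPLEMENT, revcomp

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = ("A", "C", "G", "T")

CHANNEL_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in _FLANKS
    for three in _FLANKS
)

CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNEL_LABELS)}

N_CHANNELS = 96


def channel_of(ref: str, alt: str, context: str) -> str:
    """Map a substitution plus trinucleotide context to its channel label.

    Purine-reference substitutions (ref A or G) are reverse-complemented —
    context reversed and complemented, alt complemented — so every channel has
    a pyrimidine (C or T) reference.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if context[1] != ref:
        raise ValueError(f"context {context!r} middle base != ref {ref!r}")
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        context = revcomp(context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if label not in CHANNEL_INDEX:
        raise ValueError(f"invalid channel {label!r}")
    return label


def channel_index(ref: str, alt: str, context: str) -> int:
    return CHANNEL_INDEX[channel_of(ref, alt, context)]


def channel_parts(label: str) -> tuple[str, str, str]:
    """Split ``A[C>T]G`` into (ref, alt, context)."""
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, five + ref + three
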