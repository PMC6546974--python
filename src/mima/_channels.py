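"""The 96-channel single-base-substitution coordinate system.

Substitutions are represented pyrimidine-centred: a mutation whose reference
base is a purine is reverse-complemented (ref, alt and flanking context) onto
the opposite strand.  Channels are ordered substitution-class major
(C>A, C>G, C>T, T>A, T>C, T>G), flanking context minor with the 5' base as the
outer key and the 3' base as the inner key, both alphabetical — the
conventional catalog ordering (A[C>A]A, A[C>A]C, ... T[T>G]T).
"""

from __future__ import annotations

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}

N_CHANNELS = 96


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def canonical_channel(ref: str, alt: str, context: str) -> str:
    """Map a substitution and its 3-mer context to its pyrimidine-centred channel label.

    ``context`` is the reference-strand trinucleotide centred on the mutated
    base; its middle base must equal ``ref``.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} middle base does not match ref {ref!r}")
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref!r})")
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        context = revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def channel_index(ref: str, alt: str, context: str) -> int:
    return CHANNEL_INDEX[canonical_channel(ref, alt, context)]


def channel_parts(label: str) -> tuple[str, str, str]:
    """Split ``'A[C>T]G'`` into (ref, alt, context) = ('C', 'T', 'ACG')."""
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, five + ref + three
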