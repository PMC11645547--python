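"""Shared fixtures: all corpora are generated programmatically."""

from __future__ import annotations

import random

import pytest

from seqzip.synthgen import GeneratorSpec, generate_symbols

SEQ_CHARS = "ACGTacgtNnRYKWSMBDHVryk"
HEADER_CHARS = "abcdefXYZ 0123|_.:-"


def make_fuzz_file(rng: random.Random) -> bytes:
    """One random well-formed FASTA or FASTQ file.

    Covers Ns, IUPAC codes, lowercase, ragged line lengths, empty records,
    blank lines inside records and missing final newline.
    """
    fmt = rng.choice(["fasta", "fastq"])
    parts: list[str] = []
    for _ in range(rng.randint(1, 6)):
        n = rng.choice([0, rng.randint(1, 40), rng.randint(40, 400)])
        seq = "".join(rng.choice(SEQ_CHARS) for _ in range(n))
        header = "".join(rng.choice(HEADER_CHARS) for _ in range(rng.randint(0, 25)))
        if fmt == "fasta":
            width = rng.randint(1, 90)
            lines = [seq[i : i + width] for i in range(0, len(seq), width)]
            if rng.random() < 0.2:
                lines.insert(rng.randint(0, len(lines)), "")  # blank line
            parts.append(">" + header + "\n" + "".join(l + "\n" for l in lines))
        else:
            qual = "".join(chr(rng.randint(33, 104)) for _ in range(n))
            plus = header if rng.random() < 0.3 else ""
            parts.append(f"@{header}\n{seq}\n+{plus}\n{qual}\n")
    data = "".join(parts)
    if fmt == "fasta" and data.endswith("\n") and rng.random() < 0.2:
        data = data[:-1]  # no final newline
    return data.encode("latin-1")


@pytest.fixture(scope="session")
def tandem_fixture():
    """1 kb unit tiled 200x with 0.1% substitutions (the repeat corpus)."""
    return generate_symbols(
        GeneratorSpec(
            kind="tandem_repeat",
            unit_length=1000,
            copies=200,
            substitution_rate=0.001,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def markov_fixture_small():
    """Order-2 Markov corpus at moderate length for unit-level checks."""
    return generate_symbols(GeneratorSpec(kind="markov", n=200_000, order=2, seed=5))


@pytest.fixture(scope="session")
def iid_small():
    return generate_symbols(GeneratorSpec(kind="iid", n=100_000, seed=7))
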