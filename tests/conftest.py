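import random

import pytest

from ribodyn.energy import EnergyParams
from ribodyn.kinetics import apply_move, elementary_moves


@pytest.fixture(scope="session")
def params():
    return EnergyParams()  # 315 K, Turner-99


def random_structure(seq: str, rng: random.Random, n_moves: int = 30) -> str:
    """Random valid structure by a random sequence of close moves."""
    db = "." * len(seq)
    for _ in range(n_moves):
        closers = [m for m in elementary_moves(seq, db) if m[0] > 0]
        if not closers or rng.random() < 0.2:
            if rng.random() < 0.5:
                openers = [m for m in elementary_moves(seq, db) if m[0] < 0]
                if openers:
                    db = apply_move(db, rng.choice(openers))
            continue
        db = apply_move(db, rng.choice(closers))
    return db


def random_sequence(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(n))
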