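"""Generate the frozen k-mer score panels under tests/data/.

Run once to (re)create the fixtures. The expected scores are computed here
with plain position-weight-matrix arithmetic — log2(p_signal / p_background)
summed per position — deliberately independent of the package's factored
scoring machinery, so the frozen panel can act as a dual-route oracle for
model evaluation, serialization and table loading.
"""

import math
import random
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from mesplice.fixtures import ACCEPTOR_PWM, DONOR_PWM  # data only, no scoring

BASES = "ACGT"
SEED = 20240901
N_RANDOM = 80
N_SIGNAL_LIKE = 20  # consensus-dinucleotide k-mers, exercising high scores


def naive_score(seq, pwm):
    total = 0.0
    for i, b in enumerate(seq):
        p = max(pwm[i][BASES.index(b)], 1e-9)
        total += math.log2(p / 0.25)
    return total


def consensus_like(rng, pwm, dinuc, offsets):
    seq = []
    for row in pwm:
        # draw from the PWM itself so strong motifs are represented
        r = rng.random()
        acc = 0.0
        for b, p in zip(BASES, row):
            acc += p
            if r <= acc:
                seq.append(b)
                break
        else:
            seq.append("T")
    for off, b in zip(offsets, dinuc):
        seq[off] = b
    return "".join(seq)


def build_panel(pwm, k, dinuc, offsets, rng):
    panel = ["".join(rng.choice(BASES) for _ in range(k))
             for _ in range(N_RANDOM)]
    panel += [consensus_like(rng, pwm, dinuc, offsets)
              for _ in range(N_SIGNAL_LIKE)]
    return [(seq, naive_score(seq, pwm)) for seq in panel]


def main():
    out_dir = Path(__file__).resolve().parent.parent / "tests" / "data"
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(SEED)
    panels = {
        "panel_donor.tsv": build_panel(DONOR_PWM, 9, "GT", (3, 4), rng),
        "panel_acceptor.tsv": build_panel(ACCEPTOR_PWM, 23, "AG", (18, 19), rng),
    }
    for name, rows in panels.items():
        path = out_dir / name
        with open(path, "w") as fh:
            fh.write("# frozen k-mer score panel; expected scores computed by\n")
            fh.write("# scripts/make_panel_fixture.py (naive PWM arithmetic)\n")
            fh.write("sequence\texpected_score\n")
            for seq, score in rows:
                fh.write(f"{seq}\t{score:.6f}\n")
        print(f"wrote {len(rows)} rows -> {path}")


if __name__ == "__main__":
    main()
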