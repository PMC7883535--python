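#!/usr/bin/env python
"""Regenerate the packaged default detection model.

Trains the logistic RT detector on the seeded synthetic training suite
and writes src/revtrig/data/default_model.json.  Run from the repository
root:

    python scripts/train_default_model.py [--seed 0]
"""

import argparse
from pathlib import Path

from revtrig.rt_detector import train_default_model


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument(
        "--out",
        type=Path,
        default=Path(__file__).resolve().parents[1] / "src" / "revtrig" / "data" / "default_model.json",
    )
    args = ap.parse_args()
    model = train_default_model(seed=args.seed)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    model.to_json(args.out)
    print(f"cutoff={model.cutoff:.4f} n_train={model.training_meta.get('n_train')} -> {args.out}")


if __name__ == "__main__":
    main()
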