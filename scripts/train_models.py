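#!/usr/bin/env python
"""Regenerate the shipped classifier fixtures.

Trains the vessel-pixel color classifier and the red-lesion candidate
classifier on generator-labeled synthetic scenes with fixed seeds, and
writes them as versioned JSON records under ``src/fundusdr/models/``.

Usage:  python scripts/train_models.py [--seed 0] [--out src/fundusdr/models]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from fundusdr._models import fit_linear_model
from fundusdr.anatomy import build_vessel_corpus
from fundusdr.lesions import build_candidate_corpus, train_candidate_classifier


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("src/fundusdr/models"))
    ap.add_argument("--n-scenes", type=int, default=6)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    print("building vessel pixel corpus ...")
    X, y, names = build_vessel_corpus(n_scenes=args.n_scenes, seed=args.seed)
    model = fit_linear_model(
        X, y, names, args.seed, metadata={"task": "vessel_pixel", "n_scenes": args.n_scenes}
    )
    path = args.out / "vessel_pixel.json"
    model.to_json(path)
    print(f"  wrote {path}  (n={len(y)}, vessel frac={(y == 'vessel').mean():.3f})")

    print("building red-lesion candidate corpus ...")
    corpus = build_candidate_corpus(n_scenes=args.n_scenes, seed=args.seed)
    clf = train_candidate_classifier(corpus, args.seed)
    path = args.out / "red_candidate.json"
    clf.to_json(path)
    labels = [lab for _, lab in corpus]
    frac = sum(1 for l in labels if l == "lesion") / len(labels)
    print(f"  wrote {path}  (n={len(corpus)}, lesion frac={frac:.3f})")


if __name__ == "__main__":
    main()
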