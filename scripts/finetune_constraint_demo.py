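#!/usr/bin/env python
"""Qualitative demo: grafting the synonym constraint onto an already
unconstrained-pretrained model vs training with it from scratch.

Trains a small unconstrained model, then continues training it WITH the
constraint for a few epochs, and compares its constrained loss/accuracy to
a twin trained with the constraint end to end on the same budget. Prints a
table; makes no tested claim — the point is to show that a model can be
"converted" late but does not catch the from-scratch run on equal budget.

Run: python scripts/finetune_constraint_demo.py [--seed 0]
"""

import argparse

import numpy as np

from syncodon import CodonTokenizer, TrainConfig, build_synonym_mask
from syncodon.model import init_model, EncoderConfig
from syncodon.pretraining import evaluate_masked, train
from syncodon.synthetic import make_corpus, make_species_profiles


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--epochs", type=int, default=10)
    args = parser.parse_args()

    profiles = make_species_profiles(4, 2, seed=args.seed, wobble_persistence=0.85)
    corpus = make_corpus(profiles, 150, protein_length=40, seed=args.seed + 1,
                         aa_persistence=0.6)
    tok = CodonTokenizer(max_positions=64)
    mm = build_synonym_mask(tok)
    seqs = [tok.encode(r.sequence) for r in corpus]
    tids = [0] * len(seqs)
    cfg = EncoderConfig(64, 256, 2, 4, max_positions=64, num_token_types=2,
                        relative_position_buckets=32, dtype="float32")

    def run(label, phases):
        state = init_model(cfg, seed=args.seed)
        for constraint, epochs in phases:
            tc = TrainConfig(epochs=epochs, max_lr=1e-3, seed=args.seed,
                             constraint_enabled=constraint,
                             token_type_mode="none")
            train(state, seqs, tids, tc, tok, mm)
        loss, acc = evaluate_masked(state, seqs, tids, tok, mm,
                                    seed=args.seed + 9)
        print(f"{label:<38s} constrained loss {loss:.4f}  accuracy {acc:.4f}")
        return loss, acc

    half = args.epochs // 2
    print(f"{len(seqs)} CDS, {args.epochs} total epochs each\n")
    run("constrained from scratch", [(True, args.epochs)])
    run(f"unconstrained {args.epochs - half} ep + constrained {half} ep",
        [(False, args.epochs - half), (True, half)])
    run("unconstrained only", [(False, args.epochs)])


if __name__ == "__main__":
    main()
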