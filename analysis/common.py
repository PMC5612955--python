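"""Shared argument handling for the numbered analysis drivers."""

import argparse

from xistquant.config import default_config


def get_config(description: str):
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=0, help="master random seed")
    parser.add_argument("--outdir", default="results/pipeline",
                        help="pipeline output directory")
    args = parser.parse_args()
    return default_config(seed=args.seed, outdir=args.outdir)
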