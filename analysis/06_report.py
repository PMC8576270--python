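"""Render the figure-level summary report for a completed run."""

import argparse

from inflammeth.pipeline import report


def main(outdir: str = "results/run") -> None:
    print(report(outdir))


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", default="results/run")
    args = ap.parse_args()
    main(args.outdir)
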