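"""Regenerate the bundled synthetic cytoband tables.

Writes ``src/cnaburden/data/cytoBand_<build>.synthetic.txt`` for each supported
build. The tables are deterministic functions of the assembly chromosome
lengths and approximate centromere positions embedded in ``cnaburden.genome``;
rerunning this script reproduces them byte-identically.
"""

from pathlib import Path

from cnaburden.genome import SUPPORTED_BUILDS, synthesize_cytobands

OUT = Path(__file__).resolve().parent.parent / "src" / "cnaburden" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for build in SUPPORTED_BUILDS:
        bands = synthesize_cytobands(build)
        path = OUT / f"cytoBand_{build}.synthetic.txt"
        bands.to_csv(path, sep="\t", header=False, index=False)
        print(f"wrote {path} ({len(bands)} rows)")


if __name__ == "__main__":
    main()
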