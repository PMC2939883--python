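"""Domain-architecture census of the Arabidopsis CC-TPR positives.

Joins the clamp verdicts to the protein-property table and counts positives
per architecture class (single/multiple TPR domains, with/without another
functional domain), split by novelty. The novel set should census 8/7/3/6.
"""
import json
from pathlib import Path

from cctpr.clamp import architecture_census
from cctpr.screen import classify_fixture_proteins
from cctpr.seqio import load_arabidopsis_metadata, load_arabidopsis_motifs

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    verdicts = classify_fixture_proteins(load_arabidopsis_motifs())
    meta = load_arabidopsis_metadata()
    census = architecture_census(verdicts, meta)
    (OUT / "architecture_census.json").write_text(
        json.dumps(census, indent=2) + "\n")
    novel = sum(census["novel"].values())
    known = sum(census["known"].values())
    print(f"novelty split: {novel} novel / {known} previously characterized")
    for subset in ("novel", "known"):
        print(f"{subset}: " + ", ".join(
            f"{cls}={n}" for cls, n in census[subset].items()))
    print("-> results/architecture_census.json")


if __name__ == "__main__":
    main()
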