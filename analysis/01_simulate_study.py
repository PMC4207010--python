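#!/usr/bin/env python
"""Generate the synthetic study all downstream analyses run on.

Writes a modular interactome (five modules of 14, 12, 10, 8 and 6 genes in
a 200-gene sparse background — heterogeneous sizes so the segmentation has
density contrast to work with), one omics signature per module, a
six-member drug-signature family with a planted >=2-support consensus
core, module pathways, an ortholog map and biomarker/target candidate
lists under results/study/.
"""

import json
from pathlib import Path

from procmod import synth

STUDY_SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    config = synth.SynthConfig(
        seed=STUDY_SEED,
        modules=[14, 12, 10, 8, 6],
        p_in=0.9,
        p_out=0.005,
        n_background=200,
        signature_coverage=0.9,
    )
    manifest = synth.write_study(config, ROOT / "results" / "study")
    (ROOT / "results" / "study" / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    print(f"synthetic study written to {manifest['outdir']}")
    print(f"  interactome: {manifest['n_nodes']} genes, {manifest['n_edges']} interactions")
    print(f"  {manifest['n_signatures']} omics signatures, "
          f"{manifest['n_drug_signatures']} drug signatures "
          f"(planted consensus core: {manifest['core_size']} genes)")
    print(f"  {manifest['n_pathways']} pathway annotations; seed={manifest['seed']}")


if __name__ == "__main__":
    main()
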