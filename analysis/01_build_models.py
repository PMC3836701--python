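#!/usr/bin/env python
"""Build the toy binding models (charged and uncharged) and record their
ground truth: structures, topologies, contact lists and charge tables.

Writes results/models/: PDB fixtures, topology JSON files, and CSV contact
tables.  Everything downstream (02, 03, 04) starts from these files.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from idpgo.studies import ToyStudyConditions, build_toy_model
from idpgo.synthetic import default_binding_toy, make_toy_complex

OUT = Path(__file__).resolve().parents[1] / "results" / "models"
OUT.mkdir(parents=True, exist_ok=True)

cond = ToyStudyConditions()
for charged in (False, True):
    label = "charged" if charged else "uncharged"
    pdb_text, truth = make_toy_complex(default_binding_toy(charged=charged))
    (OUT / f"toy_{label}.pdb").write_text(pdb_text)
    (OUT / f"toy_{label}_truth.json").write_text(json.dumps(truth, indent=1))

    top = build_toy_model(charged, cond)
    top.save(OUT / f"toy_{label}_topology.json")
    rows = [{"i": c.i, "j": c.j, "r_native_A": round(c.r_native, 3),
             "epsilon_kcal_mol": round(c.epsilon, 4), "class": c.kind}
            for c in top.contacts]
    pd.DataFrame(rows).to_csv(OUT / f"toy_{label}_contacts.csv", index=False)
    print(f"{label}: {top.n_particles} beads, "
          f"{len(top.intra_contacts)} intra + {len(top.inter_contacts)} inter "
          f"contacts, net charge {top.net_charge():+.0f} "
          f"(lambda_inter = {top.lambda_inter})")
print(f"written to {OUT}")
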