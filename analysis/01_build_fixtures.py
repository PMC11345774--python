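#!/usr/bin/env python
"""Build the synthetic study set: 82 nonbasic actives, the decoy universe,
the reference query (full and reduced) and the receptor-pocket fixture.

Writes the active SMILES list, the query files, the pocket PDB/pose and a
manifest with universe statistics to results/fixtures/.
"""

import json
from pathlib import Path

from korscreen import chem, fixtures

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = fixtures.FixtureSpec(seed=SEED, n_actives=82, decoys_per_active=50)
    actives, universe = fixtures.make_compound_fixture(spec)
    chem.write_smiles(actives, OUT / "actives.smi")
    fixtures.reference_query(spec, reduced=False).save(OUT / "sala_kor_full.json")
    fixtures.reference_query(spec, reduced=True).save(OUT / "sala_kor_reduced.json")
    fixtures.make_pocket_fixture(spec, OUT)

    mw = [r.descriptors["MW"] for r in actives]
    manifest = {
        "seed": SEED,
        "n_actives": len(actives),
        "universe_size": len(universe),
        "active_mw_min": round(min(mw), 1),
        "active_mw_max": round(max(mw), 1),
        "all_actives_nonbasic": all(
            not r.flags["is_charged"] and not r.flags["has_basic_amine"] for r in actives
        ),
    }
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=1))
    print(f"actives: {manifest['n_actives']} (MW {manifest['active_mw_min']}-{manifest['active_mw_max']} Da)")
    print(f"decoy universe: {manifest['universe_size']} candidates")
    print(f"all actives nonbasic: {manifest['all_actives_nonbasic']}")


if __name__ == "__main__":
    main()
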