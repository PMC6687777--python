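"""Pan-model construction, strain-specific carving, and core intersection."""

from pangem import (
    OrthologEntry,
    build_core,
    build_pan_model,
    carve_all,
)
from pangem import fixtures as fx
from pangem.pan import carve_summary

base = fx.make_toy_gem()

# Merge an ortholog of a complex subunit: the whole AND clause is duplicated.
pan = build_pan_model(base, [OrthologEntry("gC1a", "PANC1", identity=0.92)])
print("merged GPR:", pan.get_reaction("R_cplx1").gpr.to_string())
# (gC1a and gC1b) or (PANC1 and gC1b) — the ortholog can replace gC1a.

matrix = fx.make_presence_matrix(pan, n_strains=6, seed=4, dropout=0.3)
strains = carve_all(pan, matrix)
print(carve_summary(strains))
# strain000 is the all-present reference and reproduces the pan-model;
# the others lose reactions whose GPR went false (complex subunit missing)
# but keep isoenzyme reactions with a pruned rule.

result = build_core(strains.values())
print(f"core: {len(result.core.reactions)} reactions, "
      f"{len(result.core.genes)} genes; "
      f"variable: {sorted(result.variable_reactions)}")
# the core is the exact id-level intersection across all strains; a
# reaction can stay in the core even when one of its isoenzyme genes is
# variable, because the other isoenzyme covers for it.
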