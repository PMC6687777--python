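"""Build a toy genome-scale model, maximize growth, and run sanity checks."""

from pangem import apply_medium, check_mass_balance, fba, find_dead_ends, fva
from pangem import fixtures as fx

model = fx.make_toy_gem()
medium = fx.minimal_medium(model, uptake=10.0)  # glucose at 10 mmol/gDW/h

sol = fba(apply_medium(model, medium))
print(f"max growth rate: {sol.objective_value:.3f} /h")
# 10.0: one glucose yields two precursor units and biomass consumes two,
# so growth is stoichiometrically pinned to the uptake bound.

ranges = fva(apply_medium(model, medium), sol.objective_value)
width = sum(hi - lo for lo, hi in ranges.values())
print(f"summed flux variability at optimal growth: {width:.4f}")
# 0.0: the toy has a single route, so every flux is uniquely determined.

print(f"dead-end metabolites: {sorted(find_dead_ends(model))}")
# ['dead_c']: the generator plants one metabolite that is only produced.

unbalanced = [(r, el) for r, el, _ in check_mass_balance(model)]
print(f"mass-balance flags: {unbalanced}")
# only the biomass pseudo-reaction, whose product has no elemental formula.
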