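"""Substrate screens, gene essentiality and validation statistics."""

from pangem import (
    Medium,
    Metabolite,
    Reaction,
    SubstrateEntry,
    gene_essentiality,
    score_predictions,
    substrate_screen,
)
from pangem import fixtures as fx

model = fx.make_toy_gem()
model.add_metabolite(Metabolite("xyl_e", compartment="e"))
model.add_reaction(Reaction("EX_xyl", {"xyl_e": -1.0}, lower_bound=0.0))

panel = [
    SubstrateEntry("glucose", "EX_glc", "carbon"),
    SubstrateEntry("fructose", "EX_fru", "carbon"),
    SubstrateEntry("xylose", "EX_xyl", "carbon"),
]
calls = substrate_screen(model, panel, Medium())
print("substrate calls:", calls)
# glucose and fructose support growth; xylose has no consuming pathway.

observed = {"glucose": True, "fructose": True, "xylose": False}
predicted = {k: v == "growth" for k, v in calls.items()}
cm, accuracy, mcc = score_predictions(predicted, observed)
print(f"TP={cm.tp} TN={cm.tn} FP={cm.fp} FN={cm.fn} "
      f"accuracy={accuracy:.2f} MCC={mcc:.2f}")
# perfect agreement on this panel: accuracy 1.00, MCC 1.00.

essential = gene_essentiality(model, fx.minimal_medium(model))
print("essential genes:", sorted(essential))
# complex subunits and single-route genes are essential; isoenzymes
# (gI1a/gI1b) and the fructose-path genes are not.
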