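"""Score polymer-lipid hybrid formulations.

A branched poly(beta-amino ester) is represented by two extra catalogue
molecules -- its diacrylate-amine repeat unit (carrying the polymer's
molar percentage, estimated from mass over repeat-unit molar mass) and
its branching agent (identity only, 0 molar %) -- and scored by the
same network with two extra component-type embeddings.
"""

from formucomet import CometConfig, Formulation, sample_catalogue
from formucomet.encoders import FormulationTokenizer
from formucomet.formulation import Catalogue, ComponentClass, MoleculeRecord
from formucomet.model import CometModel
from formucomet.pbae import PbaeRecord, pbae_formulation, pbae_molar_percent

repeat = MoleculeRecord(
    "PB1-repeat", "CCOC(=O)CCN(C)CCC(=O)OCC", ComponentClass.PBAE_REPEAT, molar_mass=500.0
)
branch = MoleculeRecord("PB1-branch", "NCCN(CCN)CCN", ComponentClass.PBAE_BRANCH)
polymer = PbaeRecord(
    pbae_id="PB1", repeat_unit=repeat, branch_agent=branch,
    repeat_unit_molar_mass=500.0, polymer_mass_mg=1.0,
)

lipid_moles = 0.006  # mmol of lipids mixed with 1 mg polymer
print(f"PBAE molar share: {pbae_molar_percent(polymer, lipid_moles):.1f}%")

catalogue = Catalogue(list(sample_catalogue(seed=0)) + [repeat, branch])
hybrid = pbae_formulation(
    polymer,
    lipid_components=(
        ("IL-MC3", 35.0), ("HL-DOPE", 16.0), ("ST-CHOL", 46.5), ("PEG-C14", 2.5),
    ),
    lipid_moles=lipid_moles,
    np_ratio=6.0,
)
print("hybrid composition:", [(m, round(p, 2)) for m, p in hybrid.components])

tokenizer = FormulationTokenizer(catalogue)
model = CometModel(CometConfig(tasks=["efficacy"], seed=0), tokenizer)
print(f"token count: {tokenizer.tokenize(hybrid, ['efficacy']).n_tokens} "
      "(6 components + N/P + phase + CLS)")
print(f"untrained score: {model.forward_score(hybrid, 'efficacy'):+.3f}")
# Molar percentages (lipids rescaled + polymer share) sum to 100; the
# branching agent contributes structure information at 0 molar %.
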