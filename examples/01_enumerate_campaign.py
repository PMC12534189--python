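"""Enumerate the bundled four-part screening campaign.

Builds the 7 ionizable x 3 sterol x 2 helper x 2 PEG design grid with
its 13 named molar ratios and counts each part of the campaign.
"""

from formucomet.grids import (
    all_molar_compositions,
    campaign_grid,
    campaign_part_manifests,
    enumerate_dual_il,
    enumerate_single_il,
)

grid = campaign_grid()
print(f"lipid combinations:        {grid.lipid_combination_count}")
print(f"part 1 possible LNPs:      {sum(1 for _ in enumerate_single_il(grid))}")
print(f"part 2 dual-ionizable:     {sum(1 for _ in enumerate_dual_il(grid))}")
parts = campaign_part_manifests()
print(f"part 1 unique (tested-overlap): {parts[0].unique}")
print(f"total screened LNPs:       {sum(p.unique for p in parts)}")
print(f"distinct molar compositions: {len(all_molar_compositions(grid))}")
# 84 lipid choices x 13 ratios = 1,092 candidate four-lipid particles;
# 49 ordered ionizable pairs x 13 ratios = 637 dual-ionizable ones; the
# 85 compositions are 13 base ratios plus 3 x 24-point molar sweeps.
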