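"""Parse lipid shorthand names and count saponifiable acyl slots.

Shows how sum-composition names, resolved molecular species, ether lipids
and sphingolipids parse, and how the acyl-multiplicity counter treats each:
only ester-bound chains on hydrolysable classes count toward the
esterified pool of a fatty acid.
"""

from lipidtiers import AcylChain, acyl_multiplicity, parse_lipid_name

names = [
    "TG 52:3",                  # sum composition: acyls unresolved
    "DG 36:3(18:2_18:1)",       # resolved molecular species
    "TG 54:3(18:1_18:1_18:1)",  # one FA occupying all three slots
    "PE O-38:6(O-18:2_20:4)",   # ether lipid: O-chain is not ester-bound
    "SM 33:1;O2",               # sphingolipid, N-acyl resists hydrolysis
    "Cer d18:1/17:0",           # sphingoid base + resolved N-acyl
]

oleate = AcylChain(18, 1)
linoleate = AcylChain(18, 2)
margarate = AcylChain(17, 0)

print(f"{'name':28} {'level':20} {'x 18:1':>7} {'x 18:2':>7} {'x 17:0':>7}")
for name in names:
    sp = parse_lipid_name(name)
    counts = [acyl_multiplicity(sp, fa) for fa in (oleate, linoleate, margarate)]
    print(f"{name:28} {sp.level:20} {counts[0]:>7} {counts[1]:>7} {counts[2]:>7}")

print()
print("Each count is the number of saponifiable (alkali-releasable) chains")
print("matching the query FA; 0 for unresolved species, ether chains, and")
print("sphingolipid N-acyls, which survive alkaline hydrolysis.")
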