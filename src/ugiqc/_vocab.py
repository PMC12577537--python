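"""Built-in building-block SMILES vocabularies for the synthetic generator.

Small, hand-curated, license-free lists of common commercial aldehydes and
isocyanides. Each entry carries exactly one reactive group of its role
(strict monofunctionality), parses to one connected molecule, and spans a
realistic spread of size and polarity so that descriptor-driven outcome
simulation has signal to work with.
"""

ALDEHYDE_SMILES: tuple[str, ...] = (
    "C=O",                          # formaldehyde
    "CC=O",                         # acetaldehyde
    "CCC=O",                        # propanal
    "CCCC=O",                       # butanal
    "CC(C)C=O",                     # isobutyraldehyde
    "CC(C)(C)C=O",                  # pivaldehyde
    "CCCCC=O",                      # valeraldehyde
    "CCCCCC=O",                     # hexanal
    "CCCCCCC=O",                    # heptanal
    "CCCCCCCC=O",                   # octanal
    "CC(C)CC=O",                    # 3-methylbutanal
    "CCC(CC)C=O",                   # 2-ethylbutanal
    "O=CC1CC1",                     # cyclopropanecarboxaldehyde
    "O=CC1CCC1",                    # cyclobutanecarboxaldehyde
    "O=CC1CCCC1",                   # cyclopentanecarboxaldehyde
    "O=CC1CCCCC1",                  # cyclohexanecarboxaldehyde
    "O=CC1CCOCC1",                  # tetrahydropyran-4-carbaldehyde
    "O=CC1CCN(C(=O)OC(C)(C)C)CC1",  # 1-Boc-piperidine-4-carbaldehyde
    "O=Cc1ccccc1",                  # benzaldehyde
    "Cc1ccccc1C=O",                 # o-tolualdehyde
    "Cc1cccc(C=O)c1",               # m-tolualdehyde
    "Cc1ccc(C=O)cc1",               # p-tolualdehyde
    "CC(C)c1ccc(C=O)cc1",           # 4-isopropylbenzaldehyde
    "CC(C)(C)c1ccc(C=O)cc1",        # 4-tert-butylbenzaldehyde
    "Fc1ccccc1C=O",                 # 2-fluorobenzaldehyde
    "Fc1cccc(C=O)c1",               # 3-fluorobenzaldehyde
    "Fc1ccc(C=O)cc1",               # 4-fluorobenzaldehyde
    "Clc1ccccc1C=O",                # 2-chlorobenzaldehyde
    "Clc1cccc(C=O)c1",              # 3-chlorobenzaldehyde
    "Clc1ccc(C=O)cc1",              # 4-chlorobenzaldehyde
    "Brc1ccc(C=O)cc1",              # 4-bromobenzaldehyde
    "Fc1ccc(C=O)cc1F",              # 2,4-difluorobenzaldehyde
    "FC(F)(F)c1ccc(C=O)cc1",        # 4-(trifluoromethyl)benzaldehyde
    "FC(F)(F)c1cccc(C=O)c1",        # 3-(trifluoromethyl)benzaldehyde
    "COc1ccccc1C=O",                # 2-methoxybenzaldehyde
    "COc1cccc(C=O)c1",              # 3-methoxybenzaldehyde
    "COc1ccc(C=O)cc1",              # 4-methoxybenzaldehyde
    "COc1ccc(C=O)cc1OC",            # 3,4-dimethoxybenzaldehyde
    "CSc1ccc(C=O)cc1",              # 4-(methylthio)benzaldehyde
    "N#Cc1ccc(C=O)cc1",             # 4-cyanobenzaldehyde
    "O=Cc1ccc2ccccc2c1",            # 2-naphthaldehyde
    "O=Cc1cccc2ccccc12",            # 1-naphthaldehyde
    "O=CCc1ccccc1",                 # phenylacetaldehyde
    "O=CCCc1ccccc1",                # hydrocinnamaldehyde
    "O=Cc1ccco1",                   # furfural
    "Cc1ccc(C=O)o1",                # 5-methylfurfural
    "O=Cc1cccs1",                   # thiophene-2-carboxaldehyde
    "O=Cc1ccsc1",                   # thiophene-3-carboxaldehyde
    "Cn1cccc1C=O",                  # 1-methylpyrrole-2-carboxaldehyde
    "O=Cc1cccnc1",                  # nicotinaldehyde
    "O=Cc1ccncc1",                  # isonicotinaldehyde
    "O=Cc1ccccn1",                  # picolinaldehyde
    "COc1ccc(CC=O)cc1",             # 4-methoxyphenylacetaldehyde
    "Fc1ccc(CC=O)cc1",              # 4-fluorophenylacetaldehyde
    "O=CC1CCCCCC1",                 # cycloheptanecarboxaldehyde
    "CCOc1ccc(C=O)cc1",             # 4-ethoxybenzaldehyde
)

ISOCYANIDE_SMILES: tuple[str, ...] = (
    "[C-]#[N+]C",                       # methyl isocyanide
    "[C-]#[N+]CC",                      # ethyl isocyanide
    "[C-]#[N+]CCC",                     # n-propyl isocyanide
    "[C-]#[N+]C(C)C",                   # isopropyl isocyanide
    "[C-]#[N+]CCCC",                    # n-butyl isocyanide
    "[C-]#[N+]C(C)(C)C",                # tert-butyl isocyanide
    "[C-]#[N+]C(C)CC",                  # sec-butyl isocyanide
    "[C-]#[N+]CC(C)C",                  # isobutyl isocyanide
    "[C-]#[N+]CCCCC",                   # n-pentyl isocyanide
    "[C-]#[N+]CCCCCC",                  # n-hexyl isocyanide
    "[C-]#[N+]CC(C)(C)C",               # neopentyl isocyanide
    "[C-]#[N+]CCC(C)C",                 # isopentyl isocyanide
    "[C-]#[N+]C(C)(C)CC(C)(C)C",        # 1,1,3,3-tetramethylbutyl isocyanide
    "[C-]#[N+]C1CC1",                   # cyclopropyl isocyanide
    "[C-]#[N+]C1CCC1",                  # cyclobutyl isocyanide
    "[C-]#[N+]C1CCCC1",                 # cyclopentyl isocyanide
    "[C-]#[N+]C1CCCCC1",                # cyclohexyl isocyanide
    "[C-]#[N+]C1CCCCCC1",               # cycloheptyl isocyanide
    "[C-]#[N+]CC1CCCCC1",               # cyclohexylmethyl isocyanide
    "[C-]#[N+]C12CC3CC(CC(C3)C1)C2",    # 1-adamantyl isocyanide
    "[C-]#[N+]Cc1ccccc1",               # benzyl isocyanide
    "[C-]#[N+]CCc1ccccc1",              # phenethyl isocyanide
    "[C-]#[N+]C(C)c1ccccc1",            # 1-phenylethyl isocyanide
    "[C-]#[N+]C(C)(C)c1ccccc1",         # cumyl isocyanide
    "[C-]#[N+]Cc1ccc(C)cc1",            # 4-methylbenzyl isocyanide
    "[C-]#[N+]Cc1ccc(F)cc1",            # 4-fluorobenzyl isocyanide
    "[C-]#[N+]Cc1ccc(Cl)cc1",           # 4-chlorobenzyl isocyanide
    "[C-]#[N+]Cc1ccccc1Cl",             # 2-chlorobenzyl isocyanide
    "[C-]#[N+]Cc1ccc(OC)cc1",           # 4-methoxybenzyl isocyanide
    "[C-]#[N+]Cc1ccc(OC)cc1OC",         # 3,4-dimethoxybenzyl isocyanide
    "[C-]#[N+]c1ccccc1",                # phenyl isocyanide
    "[C-]#[N+]c1ccc(C)cc1",             # p-tolyl isocyanide
    "[C-]#[N+]c1ccc(F)cc1",             # 4-fluorophenyl isocyanide
    "[C-]#[N+]c1ccc(Cl)cc1",            # 4-chlorophenyl isocyanide
    "[C-]#[N+]c1ccc(OC)cc1",            # 4-methoxyphenyl isocyanide
    "[C-]#[N+]c1ccccc1C",               # o-tolyl isocyanide
    "[C-]#[N+]c1cccc(C)c1",             # m-tolyl isocyanide
    "[C-]#[N+]c1c(C)cccc1C",            # 2,6-dimethylphenyl isocyanide
    "[C-]#[N+]c1ccc(Br)cc1",            # 4-bromophenyl isocyanide
    "[C-]#[N+]c1ccc2ccccc2c1",          # 2-naphthyl isocyanide
    "[C-]#[N+]CCOC",                    # 2-methoxyethyl isocyanide
    "[C-]#[N+]CCCOC",                   # 3-methoxypropyl isocyanide
    "[C-]#[N+]CCN1CCOCC1",              # 2-morpholinoethyl isocyanide
    "[C-]#[N+]CC1CCOCC1",               # (oxan-4-yl)methyl isocyanide
    "[C-]#[N+]C1CCOCC1",                # oxan-4-yl isocyanide
    "[C-]#[N+]Cc1ccco1",                # furfuryl isocyanide
    "[C-]#[N+]Cc1cccs1",                # thiophen-2-ylmethyl isocyanide
    "[C-]#[N+]CC(=O)OCC",               # ethyl isocyanoacetate
    "[C-]#[N+]CC(=O)OC",                # methyl isocyanoacetate
    "[C-]#[N+]CS(=O)(=O)c1ccc(C)cc1",   # tosylmethyl isocyanide (TosMIC)
    "[C-]#[N+]CCS(C)(=O)=O",            # 2-(methylsulfonyl)ethyl isocyanide
    "[C-]#[N+]CC=C",                    # allyl isocyanide
    "[C-]#[N+]CCCl",                    # 2-chloroethyl isocyanide
    "[C-]#[N+]C(C)CCC",                 # pentan-2-yl isocyanide
    "[C-]#[N+]Cc1ccc(C(F)(F)F)cc1",     # 4-(trifluoromethyl)benzyl isocyanide
    "[C-]#[N+]CCc1ccc(OC)cc1",          # 4-methoxyphenethyl isocyanide
)
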