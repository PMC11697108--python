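# Harmonized compartment vocabulary for the five localization predictors.
# Keys are raw tool labels (matched case-insensitively after stripping);
# values are harmonized compartments:
#   cell_membrane, plastid, mitochondrion, golgi, er, endomembrane_other,
#   vacuole_lysosome, nucleus, cytosol, extracellular
# Edit or extend for other tool vocabularies.
"cell membrane": cell_membrane
"plasma membrane": cell_membrane
"plas": cell_membrane
"plastid": plastid
"chloroplast": plastid
"chlo": plastid
"ctp": plastid
"mitochondrion": mitochondrion
"mitochondria": mitochondrion
"mito": mitochondrion
"mtp": mitochondrion
"golgi apparatus": golgi
"golgi": golgi
"golg": golgi
"endoplasmic reticulum": er
"er": er
"e.r.": er
"sp": endomembrane_other
"signal peptide": endomembrane_other
"lysosome/vacuole": vacuole_lysosome
"vacuole": vacuole_lysosome
"vacu": vacuole_lysosome
"nucleus": nucleus
"nucl": nucleus
"cytoplasm": cytosol
"cyto": cytosol
"notp": cytosol
"other localisation": cytosol
"extracellular": extracellular
"extr": extracellular
"secreted": extracellular
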