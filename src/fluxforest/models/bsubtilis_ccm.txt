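# B. subtilis central carbon metabolism: glycolysis, pentose phosphate
# pathway, TCA cycle, anaplerosis via pyruvate carboxylase, gluconeogenic
# PEP carboxykinase, malic enzyme.  No Entner-Doudoroff pathway and no
# glyoxylate shunt (both absent in this organism).
@substrate glc.ext
@symmetric suc fum

upt: glc.ext (abcdef) -> g6p (abcdef)

pgi: g6p (abcdef) <-> f6p (abcdef)
pfk: f6p (abcdef) -> fbp (abcdef)
fba: fbp (abcdef) <-> dhap (cba) + g3p (def)
tpi: dhap (abc) <-> g3p (abc)
gap: g3p (abc) <-> pga (abc)
eno: pga (abc) -> pep (abc)
pyk: pep (abc) -> pyr (abc)
pdh: pyr (abc) -> accoa (bc) + co2 (a)

zwf: g6p (abcdef) -> pg6 (abcdef)
gnd: pg6 (abcdef) -> ru5p (bcdef) + co2 (a)
rpe: ru5p (abcde) <-> x5p (abcde)
rpi: ru5p (abcde) <-> r5p (abcde)
tkt1: x5p (abcde) + r5p (fghij) <-> s7p (abfghij) + g3p (cde)
tkt2: x5p (abcde) + e4p (fghi) <-> f6p (abfghi) + g3p (cde)
tal: s7p (abcdefg) + g3p (hij) <-> e4p (defg) + f6p (abchij)

pyc: pyr (abc) + co2 (d) -> oaa (abcd)
pck: oaa (abcd) -> pep (abc) + co2 (d)
mae: mal (abcd) -> pyr (abc) + co2 (d)

cs: oaa (abcd) + accoa (ef) -> cit (dcbfea)
icd: cit (abcdef) -> akg (abcde) + co2 (f)
ogdh: akg (abcde) -> suc (bcde) + co2 (a)
sdh: suc (abcd) -> fum (abcd)
fum: fum (abcd) <-> mal (abcd)
mdh: mal (abcd) -> oaa (abcd)

out_g6p: g6p (abcdef) ->
out_r5p: r5p (abcde) ->
out_e4p: e4p (abcd) ->
out_pga: pga (abc) ->
out_pep: pep (abc) ->
out_pyr: pyr (abc) ->
out_accoa: accoa (ab) ->
out_oaa: oaa (abcd) ->
out_akg: akg (abcde) ->
out_co2: co2 (a) ->
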