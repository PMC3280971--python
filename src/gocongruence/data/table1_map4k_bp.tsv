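gene_id	species	aspect	term_id	term_name	origin
MAP4K2	human	P	GO:0065007	biological regulation	inferred
MAP4K3	human	P	GO:0065007	biological regulation	inferred
MAP4K2	human	P	GO:0050789	regulation of biological process	inferred
MAP4K3	human	P	GO:0050789	regulation of biological process	inferred
MAP4K2	human	P	GO:0060255	regulation of macromolecule metabolic process	inferred
MAP4K2	human	P	GO:0080090	regulation of primary metabolic process	inferred
MAP4K2	human	P	GO:0051716	cellular response to stimulus	inferred
MAP4K3	human	P	GO:0051716	cellular response to stimulus	inferred
MAP4K2	human	P	GO:0031323	regulation of cellular metabolic process	inferred
MAP4K2	human	P	GO:0050794	regulation of cellular process	inferred
MAP4K2	human	P	GO:0019222	regulation of metabolic process	inferred
MAP4K2	human	P	GO:0065009	regulation of molecular function	inferred
MAP4K2	human	P	GO:0051174	regulation of phosphorus metabolic process	inferred
MAP4K2	human	P	GO:0051246	regulation of protein metabolic process	inferred
MAP4K2	human	P	GO:0044093	positive regulation of molecular function	inferred
MAP4K2	human	P	GO:0050790	regulation of catalytic activity	inferred
MAP4K2	human	P	GO:0032268	regulation of cellular protein metabolic process	inferred
MAP4K2	human	P	GO:0019220	regulation of phosphate metabolic process	inferred
MAP4K2	human	P	GO:0009987	cellular process	inferred
Map4k2	mouse	P	GO:0009987	cellular process	inferred
MAP4K3	human	P	GO:0009987	cellular process	inferred
MAP4K2	human	P	GO:0035556	intracellular signal transduction	inferred
MAP4K3	human	P	GO:0035556	intracellular signal transduction	inferred
MAP4K2	human	P	GO:0008152	metabolic process	inferred
MAP4K3	human	P	GO:0008152	metabolic process	inferred
MAP4K2	human	P	GO:0043085	positive regulation of catalytic activity	inferred
MAP4K2	human	P	GO:0042325	regulation of phosphorylation	inferred
MAP4K2	human	P	GO:0031399	regulation of protein modification process	inferred
MAP4K2	human	P	GO:0051338	regulation of transferase activity	inferred
MAP4K2	human	P	GO:0006950	response to stress	inferred
MAP4K3	human	P	GO:0006950	response to stress	direct
MAP4K2	human	P	GO:0007154	cell communication	inferred
MAP4K3	human	P	GO:0007154	cell communication	inferred
MAP4K2	human	P	GO:0044237	cellular metabolic process	inferred
MAP4K3	human	P	GO:0044237	cellular metabolic process	inferred
MAP4K2	human	P	GO:0033554	cellular response to stress	inferred
MAP4K2	human	P	GO:0007243	intracellular protein kinase cascade	inferred
MAP4K3	human	P	GO:0007243	intracellular protein kinase cascade	direct
MAP4K2	human	P	GO:0051347	positive regulation of transferase activity	inferred
MAP4K2	human	P	GO:0044238	primary metabolic process	inferred
MAP4K3	human	P	GO:0044238	primary metabolic process	inferred
MAP4K2	human	P	GO:0043549	regulation of kinase activity	inferred
MAP4K2	human	P	GO:0001932	regulation of protein phosphorylation	inferred
MAP4K2	human	P	GO:0080134	regulation of response to stress	inferred
MAP4K2	human	P	GO:0050896	response to stimulus	inferred
MAP4K2	human	P	GO:0023052	signaling	inferred
MAP4K3	human	P	GO:0023052	signaling	inferred
MAP4K2	human	P	GO:0044260	cellular macromolecule metabolic process	inferred
MAP4K2	human	P	GO:0043170	macromolecule metabolic process	inferred
MAP4K2	human	P	GO:0000165	MAPKKK cascade	inferred
MAP4K2	human	P	GO:0006793	phosphorus metabolic process	inferred
MAP4K3	human	P	GO:0006793	phosphorus metabolic process	inferred
MAP4K2	human	P	GO:0033674	positive regulation of kinase activity	inferred
MAP4K2	human	P	GO:0019538	protein metabolic process	inferred
MAP4K3	human	P	GO:0019538	protein metabolic process	inferred
MAP4K2	human	P	GO:0080135	regulation of cellular response to stress	inferred
MAP4K2	human	P	GO:0010627	regulation of intracellular protein kinase cascade	inferred
MAP4K2	human	P	GO:0045859	regulation of protein kinase activity	inferred
MAP4K2	human	P	GO:0048583	regulation of response to stimulus	inferred
MAP4K2	human	P	GO:0023051	regulation of signaling	inferred
MAP4K2	human	P	GO:0007165	signal transduction	inferred
MAP4K3	human	P	GO:0007165	signal transduction	inferred
MAP4K2	human	P	GO:0031098	stress-activated protein kinase signaling cascade	inferred
MAP4K2	human	P	GO:0044267	cellular protein metabolic process	inferred
MAP4K3	human	P	GO:0044267	cellular protein metabolic process	inferred
MAP4K2	human	P	GO:0007254	JNK cascade	inferred
MAP4K2	human	P	GO:0043412	macromolecule modification	inferred
MAP4K3	human	P	GO:0043412	macromolecule modification	inferred
MAP4K2	human	P	GO:0006796	phosphate-containing compound metabolic process	inferred
MAP4K3	human	P	GO:0006796	phosphate-containing compound metabolic process	inferred
MAP4K2	human	P	GO:0045860	positive regulation of protein kinase activity	inferred
MAP4K2	human	P	GO:0043408	regulation of MAPKKK cascade	inferred
MAP4K2	human	P	GO:0071900	regulation of protein serine/threonine kinase activity	inferred
MAP4K2	human	P	GO:0009966	regulation of signal transduction	inferred
MAP4K2	human	P	GO:0070302	regulation of stress-activated protein kinase signaling cascade	inferred
MAP4K2	human	P	GO:0016310	phosphorylation	inferred
MAP4K3	human	P	GO:0016310	phosphorylation	inferred
MAP4K2	human	P	GO:0071902	positive regulation of protein serine/threonine kinase activity	inferred
MAP4K2	human	P	GO:0006464	protein modification process	inferred
MAP4K3	human	P	GO:0006464	protein modification process	inferred
MAP4K2	human	P	GO:0046328	regulation of JNK cascade	inferred
MAP4K2	human	P	GO:0043405	regulation of MAP kinase activity	inferred
MAP4K2	human	P	GO:0043406	positive regulation of MAP kinase activity	inferred
MAP4K2	human	P	GO:0006468	protein phosphorylation	inferred
MAP4K3	human	P	GO:0006468	protein phosphorylation	direct
MAP4K2	human	P	GO:0043506	regulation of JUN kinase activity	inferred
MAP4K2	human	P	GO:0000187	activation of MAPK activity	inferred
MAP4K2	human	P	GO:0043507	positive regulation of JUN kinase activity	inferred
MAP4K2	human	P	GO:0007257	activation of JUN kinase activity	direct
Map4k2	mouse	P	GO:0051641	cellular localization	inferred
Map4k2	mouse	P	GO:0051179	localization	inferred
Map4k2	mouse	P	GO:0051234	establishment of localization	inferred
Map4k2	mouse	P	GO:0051640	organelle localization	inferred
Map4k2	mouse	P	GO:0051649	establishment of localization in cell	inferred
Map4k2	mouse	P	GO:0051656	establishment of organelle localization	inferred
Map4k2	mouse	P	GO:0006810	transport	inferred
Map4k2	mouse	P	GO:0051648	vesicle localization	inferred
Map4k2	mouse	P	GO:0051650	establishment of vesicle localization	inferred
Map4k2	mouse	P	GO:0016192	vesicle-mediated transport	direct
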