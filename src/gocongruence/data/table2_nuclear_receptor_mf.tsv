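gene_id	species	aspect	term_id	term_name	origin
Thra	mouse	F	GO:0060089	molecular transducer activity	inferred
THRA	human	F	GO:0060089	molecular transducer activity	inferred
Esr1	mouse	F	GO:0060089	molecular transducer activity	inferred
Thra	mouse	F	GO:0001071	nucleic acid binding transcription factor activity	inferred
THRA	human	F	GO:0001071	nucleic acid binding transcription factor activity	inferred
Esr1	mouse	F	GO:0001071	nucleic acid binding transcription factor activity	inferred
Thra	mouse	F	GO:0004872	receptor activity	inferred
THRA	human	F	GO:0004872	receptor activity	inferred
Esr1	mouse	F	GO:0004872	receptor activity	inferred
Thra	mouse	F	GO:0003700	sequence-specific DNA binding transcription factor activity	inferred
THRA	human	F	GO:0003700	sequence-specific DNA binding transcription factor activity	inferred
Esr1	mouse	F	GO:0003700	sequence-specific DNA binding transcription factor activity	inferred
Thra	mouse	F	GO:0004871	signal transducer activity	inferred
THRA	human	F	GO:0004871	signal transducer activity	inferred
Esr1	mouse	F	GO:0004871	signal transducer activity	inferred
Thra	mouse	F	GO:0000981	sequence-specific DNA binding RNA polymerase II transcription factor activity	inferred
THRA	human	F	GO:0000981	sequence-specific DNA binding RNA polymerase II transcription factor activity	inferred
Esr1	mouse	F	GO:0000981	sequence-specific DNA binding RNA polymerase II transcription factor activity	inferred
Thra	mouse	F	GO:0038023	signaling receptor activity	inferred
THRA	human	F	GO:0038023	signaling receptor activity	inferred
Esr1	mouse	F	GO:0038023	signaling receptor activity	inferred
Thra	mouse	F	GO:0004879	ligand-activated sequence-specific DNA binding RNA polymerase II transcription factor activity	direct
THRA	human	F	GO:0004879	ligand-activated sequence-specific DNA binding RNA polymerase II transcription factor activity	inferred
Esr1	mouse	F	GO:0004879	ligand-activated sequence-specific DNA binding RNA polymerase II transcription factor activity	direct
THRA	human	F	GO:0004887	thyroid hormone receptor activity	direct
Thra	mouse	F	GO:0005488	binding	inferred
THRA	human	F	GO:0005488	binding	inferred
Esr1	mouse	F	GO:0005488	binding	inferred
Thra	mouse	F	GO:0005515	protein binding	direct
THRA	human	F	GO:0005515	protein binding	inferred
Esr1	mouse	F	GO:0005515	protein binding	direct
Thra	mouse	F	GO:0032403	protein complex binding	direct
THRA	human	F	GO:0008134	transcription factor binding	inferred
Esr1	mouse	F	GO:0008134	transcription factor binding	direct
THRA	human	F	GO:0017025	TBP-class protein binding	direct
THRA	human	F	GO:0019904	protein domain specific binding	direct
Thra	mouse	F	GO:0003676	nucleic acid binding	inferred
THRA	human	F	GO:0003676	nucleic acid binding	inferred
Thra	mouse	F	GO:0003723	RNA binding	inferred
Thra	mouse	F	GO:0003727	single-stranded RNA binding	inferred
Thra	mouse	F	GO:0002153	steroid receptor RNA activator RNA binding	direct
THRA	human	F	GO:0042562	hormone binding	inferred
THRA	human	F	GO:0070324	thyroid hormone binding	direct
THRA	human	F	GO:0003677	DNA binding	inferred
THRA	human	F	GO:0001067	regulatory region nucleic acid binding	inferred
THRA	human	F	GO:0000975	regulatory region DNA binding	direct
Esr1	mouse	F	GO:0003682	chromatin binding	direct
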