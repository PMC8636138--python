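generic	synonym
omeprazole	OMEPRAZOLE
omeprazole	PRILOSEC
omeprazole	LOSEC
omeprazole	ZEGERID
esomeprazole	ESOMEPRAZOLE
esomeprazole	NEXIUM
esomeprazole	NEXIAM
lansoprazole	LANSOPRAZOLE
lansoprazole	PREVACID
lansoprazole	ZOTON
lansoprazole	TAKEPRON
dexlansoprazole	DEXLANSOPRAZOLE
dexlansoprazole	DEXILANT
dexlansoprazole	KAPIDEX
rabeprazole	RABEPRAZOLE
rabeprazole	ACIPHEX
rabeprazole	PARIET
pantoprazole	PANTOPRAZOLE
pantoprazole	PROTONIX
pantoprazole	PANTOLOC
pantoprazole	CONTROLOC
pantoprazole	TECTA
ilaprazole	ILAPRAZOLE
ilaprazole	NOLTEC
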