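pt	smq_liver_injury	smq_acute_hepatic_failure	soc_hepatobiliary	category
Acute hepatic failure	1	1	1	uncategorized
Alanine aminotransferase abnormal	1	0	1	uncategorized
Alanine aminotransferase increased	1	0	1	uncategorized
Ammonia increased	1	1	1	uncategorized
Aspartate aminotransferase increased	1	0	1	uncategorized
Bilirubin conjugated increased	1	0	1	cholestasis
Blood bilirubin increased	1	0	1	uncategorized
Cholestasis	1	0	1	cholestasis
Coma hepatic	1	1	1	liver_failure
Hepatic encephalopathy	1	1	1	uncategorized
Hepatic enzyme abnormal	1	0	1	uncategorized
Hepatic enzyme increased	1	0	1	uncategorized
Hepatic failure	1	1	1	uncategorized
Hepatic function abnormal	1	0	1	hepatocellular_injury
Hepatic necrosis	1	1	1	liver_failure
Hepatitis	1	0	1	hepatocellular_injury
Hepatitis acute	1	0	1	hepatocellular_injury
Hepatitis cholestatic	1	0	1	cholestasis
Hepatitis fulminant	1	1	1	liver_failure
Hepatitis toxic	1	0	1	uncategorized
Hepatotoxicity	1	0	1	uncategorized
Hyperammonaemia	1	1	1	liver_failure
Hyperbilirubinemia	1	0	1	uncategorized
Jaundice	1	0	1	uncategorized
Jaundice cholestatic	1	0	1	cholestasis
Liver function test abnormal	1	0	1	uncategorized
Liver injury	1	0	1	hepatocellular_injury
Liver transplant	1	1	1	uncategorized
Subacute hepatic failure	1	1	1	uncategorized
Transaminases abnormal	1	0	1	uncategorized
Transaminases increased	1	0	1	hepatocellular_injury
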