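individual,element,level,cumulative_mm,annual_mm,rate_um_day,partial_year
MOR-OST 1648,fibula,hatchling,0.37,0.37,,
MOR-OST 1648,fibula,cgm1,,,,
MOR-OST 1648,fibula,cgm2,1.05,,,
MOR-OST 1648,fibula,cgm3,1.17,0.12,0.56,
MOR-OST 1648,fibula,cgm4,,,,
MOR-OST 1648,fibula,surface,1.30,0.13,0.61,True
MOR-OST 1648,femur,hatchling,0.71,0.71,,
MOR-OST 1648,femur,cgm1,,,,
MOR-OST 1648,femur,cgm2,2.20,,,
MOR-OST 1648,femur,cgm3,2.43,0.23,1.05,
MOR-OST 1648,femur,cgm4,,,,
MOR-OST 1648,femur,surface,2.81,0.38,1.78,False
MOR-OST 1648,humerus,hatchling,0.57,0.57,,
MOR-OST 1648,humerus,cgm1,,,,
MOR-OST 1648,humerus,cgm2,,,,
MOR-OST 1648,humerus,cgm3,2.01,,,
MOR-OST 1648,humerus,cgm4,,,,
MOR-OST 1648,humerus,surface,2.35,0.34,1.57,False
MOR-OST 1648,radius,hatchling,0.37,0.36,,
MOR-OST 1648,radius,cgm1,0.61,0.25,1.14,
MOR-OST 1648,radius,cgm2,0.99,0.38,1.78,
MOR-OST 1648,radius,cgm3,1.14,0.15,0.68,
MOR-OST 1648,radius,cgm4,,,,
MOR-OST 1648,radius,surface,1.30,0.17,0.77,False
MOR-OST 1648,tibia,hatchling,0.55,0.55,,
MOR-OST 1648,tibia,cgm1,,,,
MOR-OST 1648,tibia,cgm2,1.76,,,
MOR-OST 1648,tibia,cgm3,1.96,0.20,0.93,
MOR-OST 1648,tibia,cgm4,,,,
MOR-OST 1648,tibia,surface,2.24,0.28,1.31,False
MOR-OST 1648,ulna,hatchling,0.36,0.36,,
MOR-OST 1648,ulna,cgm1,,,,
MOR-OST 1648,ulna,cgm2,1.12,,,
MOR-OST 1648,ulna,cgm3,1.31,0.20,0.91,
MOR-OST 1648,ulna,cgm4,,,,
MOR-OST 1648,ulna,surface,1.52,0.21,0.98,False
MOR-OST 1649,fibula,hatchling,0.37,0.37,,
MOR-OST 1649,fibula,cgm1,,,,
MOR-OST 1649,fibula,cgm2,1.04,,,
MOR-OST 1649,fibula,cgm3,1.33,0.29,1.36,
MOR-OST 1649,fibula,cgm4,1.61,0.28,1.29,
MOR-OST 1649,fibula,cgm5,,,,
MOR-OST 1649,fibula,surface,1.86,0.26,1.19,True
MOR-OST 1649,femur,hatchling,0.71,0.71,,
MOR-OST 1649,femur,cgm1,,,,
MOR-OST 1649,femur,cgm2,1.93,,,
MOR-OST 1649,femur,cgm3,2.71,0.79,3.67,
MOR-OST 1649,femur,cgm4,3.39,0.68,3.18,
MOR-OST 1649,femur,cgm5,,,,
MOR-OST 1649,femur,surface,3.89,0.50,2.34,True
MOR-OST 1649,humerus,hatchling,0.57,0.57,,
MOR-OST 1649,humerus,cgm1,,,,
MOR-OST 1649,humerus,cgm2,1.53,,,
MOR-OST 1649,humerus,cgm3,2.14,0.61,2.85,
MOR-OST 1649,humerus,cgm4,2.70,0.56,2.62,
MOR-OST 1649,humerus,cgm5,3.14,,,
MOR-OST 1649,humerus,surface,3.20,0.50,2.36,True
MOR-OST 1649,radius,hatchling,0.37,0.36,,
MOR-OST 1649,radius,cgm1,0.96,0.59,2.76,
MOR-OST 1649,radius,cgm2,1.26,0.30,1.40,
MOR-OST 1649,radius,cgm3,1.52,0.26,1.21,
MOR-OST 1649,radius,cgm4,1.78,0.26,1.21,
MOR-OST 1649,radius,cgm5,,,,
MOR-OST 1649,radius,surface,1.84,0.06,0.30,False
MOR-OST 1649,tibia,hatchling,0.55,0.55,,
MOR-OST 1649,tibia,cgm1,,,,
MOR-OST 1649,tibia,cgm2,1.63,,,
MOR-OST 1649,tibia,cgm3,2.22,0.59,2.76,
MOR-OST 1649,tibia,cgm4,2.70,0.48,2.24,
MOR-OST 1649,tibia,cgm5,,,,
MOR-OST 1649,tibia,surface,3.15,0.45,2.10,True
MOR-OST 1649,ulna,hatchling,0.36,0.36,,
MOR-OST 1649,ulna,cgm1,,,,
MOR-OST 1649,ulna,cgm2,,,,
MOR-OST 1649,ulna,cgm3,1.43,,,
MOR-OST 1649,ulna,cgm4,1.76,0.34,1.57,
MOR-OST 1649,ulna,cgm5,2.05,,,
MOR-OST 1649,ulna,surface,2.14,0.38,1.78,True
MOR-OST 1650,fibula,hatchling,0.37,0.37,,
MOR-OST 1650,fibula,cgm1,1.04,0.66,3.10,
MOR-OST 1650,fibula,cgm2,1.29,0.26,1.19,
MOR-OST 1650,fibula,cgm3,1.60,0.31,1.46,
MOR-OST 1650,fibula,cgm4,1.73,0.13,0.60,
MOR-OST 1650,fibula,cgm5,,,,
MOR-OST 1650,fibula,surface,2.17,0.44,2.04,False
MOR-OST 1650,femur,hatchling,0.71,0.71,,
MOR-OST 1650,femur,cgm1,2.16,1.46,6.80,
MOR-OST 1650,femur,cgm2,2.57,0.41,1.93,
MOR-OST 1650,femur,cgm3,3.11,0.53,2.49,
MOR-OST 1650,femur,cgm4,3.39,0.28,1.31,
MOR-OST 1650,femur,cgm5,,,,
MOR-OST 1650,femur,surface,4.16,0.78,3.63,False
MOR-OST 1650,humerus,hatchling,0.57,0.57,,
MOR-OST 1650,humerus,cgm1,1.46,0.89,4.16,
MOR-OST 1650,humerus,cgm2,2.02,0.56,2.59,
MOR-OST 1650,humerus,cgm3,2.61,0.59,2.76,
MOR-OST 1650,humerus,cgm4,2.83,0.23,1.05,
MOR-OST 1650,humerus,cgm5,,,,
MOR-OST 1650,humerus,surface,3.65,0.82,3.83,False
MOR-OST 1650,radius,hatchling,0.37,0.36,,
MOR-OST 1650,radius,cgm1,1.04,0.67,3.14,
MOR-OST 1650,radius,cgm2,1.25,0.21,0.97,
MOR-OST 1650,radius,cgm3,1.52,0.28,1.30,
MOR-OST 1650,radius,cgm4,1.66,0.14,0.65,
MOR-OST 1650,radius,cgm5,2.04,,,
MOR-OST 1650,radius,surface,2.09,0.42,1.97,True
MOR-OST 1650,tibia,hatchling,0.55,0.55,,
MOR-OST 1650,tibia,cgm1,1.50,0.95,4.44,
MOR-OST 1650,tibia,cgm2,2.06,0.56,2.59,
MOR-OST 1650,tibia,cgm3,2.64,0.58,2.71,
MOR-OST 1650,tibia,cgm4,2.85,0.21,0.98,
MOR-OST 1650,tibia,cgm5,,,,
MOR-OST 1650,tibia,surface,3.57,0.72,3.36,False
MOR-OST 1650,ulna,hatchling,0.36,0.36,,
MOR-OST 1650,ulna,cgm1,,,,
MOR-OST 1650,ulna,cgm2,1.35,,,
MOR-OST 1650,ulna,cgm3,1.74,0.39,1.81,
MOR-OST 1650,ulna,cgm4,1.87,0.13,0.58,
MOR-OST 1650,ulna,cgm5,2.45,,,
MOR-OST 1650,ulna,surface,2.50,0.63,2.96,True
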